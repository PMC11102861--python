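"""RNA substrate definitions for in vitro deadenylation assays.

A substrate is a short 5'-labelled RNA body carrying a 3' tail that the
CCR4-NOT deadenylase removes one nucleotide at a time.  Tail positions are
counted from the 3' terminus: position ``p = 1`` is the 3'-most residue of
the full-length tail and ``p = N`` abuts the body.  Gel species are indexed
``s = 1 .. N+1`` where ``s = 1`` is the intact substrate and ``s = N+1`` the
tailless body; the removal event ``s -> s+1`` hydrolyses the residue at tail
position ``p = s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = frozenset("AGUC")

# Standard 7-mer body used throughout the assays.
DEFAULT_BODY = "UCUACAU"


@dataclass(frozen=True)
class TailSubstrate:
    """A body + tail RNA substrate with 3'-anchored tail indexing.

    Parameters
    ----------
    name : str
        Substrate label, e.g. ``"A20G"``.
    body : str
        Body sequence 5'->3' (the part that is not degraded).
    tail : str
        Tail sequence 5'->3'.  Note the 5'->3' string runs from tail
        position ``N`` down to position ``1``.
    """

    name: str
    body: str = DEFAULT_BODY
    tail: str = "A" * 20

    def __post_init__(self) -> None:
        if len(self.tail) < 1:
            raise ValueError("tail must contain at least one residue")
        bad = set(self.body + self.tail) - NUCLEOTIDES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; expected A/G/U/C")

    @property
    def tail_length(self) -> int:
        return len(self.tail)

    @property
    def n_species(self) -> int:
        """Number of gel species, tail length + 1 (the tailless body)."""
        return len(self.tail) + 1

    def residue(self, p: int) -> str:
        """Residue at tail position ``p`` counted from the 3' end (1-based)."""
        n = len(self.tail)
        if not 1 <= p <= n:
            raise ValueError(f"tail position {p} outside 1..{n}")
        return self.tail[n - p]

    def non_a_positions(self) -> list[int]:
        """Tail positions (3'-anchored) of non-adenosine residues, ascending."""
        return [p for p in range(1, len(self.tail) + 1) if self.residue(p) != "A"]

    @property
    def sequence(self) -> str:
        """Full 5'->3' sequence, body then tail."""
        return self.body + self.tail


def _mixed_tail(length: int, residue: str, positions: tuple[int, ...]) -> str:
    chars = ["A"] * length
    for p in positions:
        chars[length - p] = residue
    return "".join(chars)


def preset(name: str) -> TailSubstrate:
    """Return a named substrate preset.

    ``A20`` is the pure 20-nt poly(A) control; ``A20G``/``A20U``/``A20C``
    carry two non-A residues at tail positions 7 and 14 from the 3' end.
    ``A60`` variants are the 60-nt analogues (non-A at 7 and 14 as well).
    """
    key = name.upper()
    if key in _PRESETS:
        return _PRESETS[key]
    raise KeyError(f"unknown substrate preset {name!r}; known: {sorted(_PRESETS)}")


_PRESETS: dict[str, TailSubstrate] = {
    "A20": TailSubstrate("A20"),
    "A20G": TailSubstrate("A20G", tail=_mixed_tail(20, "G", (7, 14))),
    "A20U": TailSubstrate("A20U", tail=_mixed_tail(20, "U", (7, 14))),
    "A20C": TailSubstrate("A20C", tail=_mixed_tail(20, "C", (7, 14))),
    "A60": TailSubstrate("A60", tail="A" * 60),
    "A60G": TailSubstrate("A60G", tail=_mixed_tail(60, "G", (7, 14))),
}


def from_fasta(path, tail_length: int, name: str | None = None) -> TailSubstrate:
    """Load a substrate from a FASTA record (sequence 5'->3', body + tail).

    The tail boundary is not encoded in FASTA, so ``tail_length`` must be
    given.  DNA alphabets are accepted and T is read as U.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if name is not None:
        matches = [r for r in records if r.id == name]
        if not matches:
            raise KeyError(f"no record named {name!r} in {path}")
        rec = matches[0]
    else:
        rec = records[0]
    seq = str(rec.seq).upper().replace("T", "U")
    if tail_length >= len(seq):
        raise ValueError("tail_length must leave at least one body residue")
    return TailSubstrate(rec.id, body=seq[:-tail_length], tail=seq[-tail_length:])
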