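"""Stalling-effect quantification: adenosine-equivalents of non-A residues.

The reciprocal of a per-position removal rate is the reaction time for a
single deadenylation event, ``z_p = 1 / lam_p`` (minutes).  A non-A residue
at tail position ``r`` stalls the deadenylase over three positions —
antepenultimate (-2), penultimate (-1) and terminal (0) relative to the
residue, i.e. tail positions ``r-2``, ``r-1`` and ``r`` — so its effect is
summarized by comparing the three reaction times against a hypothetical
"no stalling" baseline built from the matched pure-poly(A) control.

Because removal also slows gradually as the tail shortens, the baseline is
constructed by assuming the gradual slowdown in the mixed-tail experiment
is proportional to that in the control:

    b        = (z(a1) - z(a2)) / (zA(a1) - zA(a2))     scaling constant
    eps(i)   = b * (zA(a1) - zA(i))                    gradual slowdown
    z0(i)    = z(a1) - eps(i)                          no-stalling baseline

with calibration anchors (a1, a2) = (-3, +2) by default, chosen outside
the stalled window.  The stalling effect size

    zeta = z(-2)/z0(-2) + z(-1)/z0(-1) + z(0)/z0(0) - 2

is the residue's adenosine-equivalent count: zeta = 1 when the mixed tail
behaves exactly like the rescaled control (a non-A that costs no more than
one ordinary adenosine removal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import RateProfile
from .substrates import TailSubstrate

__all__ = [
    "RemovalTimeProfile",
    "StallingAssessment",
    "removal_times",
    "no_stall_baseline",
    "stalling_effect",
    "assess_stalling",
    "aggregate_replicates",
    "effective_tail_length",
]

STALL_WINDOW = (-2, -1, 0)
DEFAULT_CALIBRATION = (-3, 2)


@dataclass
class RemovalTimeProfile:
    """Per-position single-event reaction times z_p = 1/lam_p (minutes).

    Positions with zero rate (or no estimate) carry NaN and are flagged in
    ``available``.
    """

    z: np.ndarray
    available: np.ndarray

    def at(self, p: int) -> float:
        """Reaction time at tail position ``p`` (1-based from the 3' end)."""
        if not 1 <= p <= self.z.size:
            raise ValueError(f"tail position {p} outside 1..{self.z.size}")
        if not self.available[p - 1]:
            raise ValueError(f"reaction time unavailable at position {p}")
        return float(self.z[p - 1])

    def relative(self, r: int, i: int) -> float:
        """z(i) anchored at a residue's tail position r: z(i) = z_{r+i}."""
        return self.at(r + i)


def removal_times(rates: RateProfile | np.ndarray) -> RemovalTimeProfile:
    """Invert rates to single-event reaction times; z = 1/lambda."""
    lam = rates.rates if isinstance(rates, RateProfile) else np.asarray(rates, float)
    if not np.any(lam > 0):
        raise ValueError("all rates are zero: no reaction times defined")
    available = lam > 0
    z = np.full(lam.shape, np.nan)
    z[available] = 1.0 / lam[available]
    return RemovalTimeProfile(z, available)


def no_stall_baseline(
    z_mixed: RemovalTimeProfile,
    z_control: RemovalTimeProfile,
    anchor: int,
    calibration: tuple[int, int] = DEFAULT_CALIBRATION,
    substrate: TailSubstrate | None = None,
) -> dict:
    """Construct the no-stalling baseline for the residue at tail position
    ``anchor`` of the mixed-tail substrate.

    ``z_control`` must come from the matched pure-poly(A) fit; positions
    are compared at the same absolute tail positions (relative indices
    shift with the anchor).  Returns ``{"b": ..., "eps": {i: ...},
    "z_null": {i: ...}}`` for i in the stalled window.
    """
    a1, a2 = calibration
    if a1 in STALL_WINDOW or a2 in STALL_WINDOW:
        raise ValueError(
            f"calibration positions {calibration} must lie outside {STALL_WINDOW}"
        )
    if a1 == a2:
        raise ValueError("calibration positions must differ")
    if substrate is not None and substrate.residue(anchor) == "A":
        raise ValueError(
            f"anchor {anchor} is an adenosine in {substrate.name}; the stalling "
            "analysis anchors at non-A residues"
        )
    z_a1, z_a2 = z_mixed.relative(anchor, a1), z_mixed.relative(anchor, a2)
    zA_a1, zA_a2 = z_control.relative(anchor, a1), z_control.relative(anchor, a2)
    denom = zA_a1 - zA_a2
    dA = {i: zA_a1 - z_control.relative(anchor, i) for i in STALL_WINDOW}
    if denom == 0:
        # A perfectly flat control has no gradual slowdown: eps(i) = b * 0 = 0
        # for every window position and b itself drops out.  Any other zero
        # denominator leaves b (and eps) undefined.
        if all(v == 0 for v in dA.values()):
            warnings.warn(
                "flat control profile: no gradual slowdown, scaling constant b "
                "is undefined and eps(i) = 0",
                stacklevel=2,
            )
            b = np.nan
            eps = {i: 0.0 for i in STALL_WINDOW}
            return {"b": b, "eps": eps, "z_null": {i: z_a1 for i in STALL_WINDOW}}
        raise ValueError(
            f"control reaction times equal at calibration positions {calibration}; "
            "choose different anchors"
        )
    b = (z_a1 - z_a2) / denom
    eps = {i: b * dA[i] for i in STALL_WINDOW}
    z_null = {i: z_a1 - eps[i] for i in STALL_WINDOW}
    return {"b": b, "eps": eps, "z_null": z_null}


def stalling_effect(z, z_null) -> float:
    """Stalling effect size zeta: sum of the three time ratios minus 2.

    ``z`` and ``z_null`` map (or list, ordered -2, -1, 0) the stalled and
    baseline reaction times.  zeta is dimensionless and reads as the
    number of adenosines whose removal takes as long as traversing the
    residue's influence zone; zeta = 1 means no stalling.
    """
    zv = [z[i] for i in STALL_WINDOW] if isinstance(z, dict) else list(z)
    z0v = [z_null[i] for i in STALL_WINDOW] if isinstance(z_null, dict) else list(z_null)
    if len(zv) != 3 or len(z0v) != 3:
        raise ValueError("need reaction times at exactly the three stalled positions")
    zv, z0v = np.asarray(zv, float), np.asarray(z0v, float)
    if np.any(z0v <= 0):
        raise ValueError("baseline reaction times must be positive")
    if np.any(zv <= 0):
        raise ValueError("stalled reaction times must be positive")
    return float(np.sum(zv / z0v) - 2.0)


@dataclass
class StallingAssessment:
    """Full stalling quantification for one non-A residue of one fit pair."""

    substrate: str
    anchor: int
    residue: str
    z: dict
    z_null: dict
    eps: dict
    b: float
    zeta: float
    calibration: tuple[int, int] = DEFAULT_CALIBRATION
    zeta_se: float | None = None

    def to_dict(self) -> dict:
        return {
            "substrate": self.substrate,
            "anchor": self.anchor,
            "residue": self.residue,
            "z": {str(k): v for k, v in self.z.items()},
            "z_null": {str(k): v for k, v in self.z_null.items()},
            "eps": {str(k): v for k, v in self.eps.items()},
            "b": self.b,
            "zeta": self.zeta,
            "calibration": list(self.calibration),
            "zeta_se": self.zeta_se,
        }


def assess_stalling(
    rates_mixed: RateProfile,
    rates_control: RateProfile,
    substrate: TailSubstrate,
    anchor: int | None = None,
    calibration: tuple[int, int] = DEFAULT_CALIBRATION,
    propagate_se: bool = False,
) -> list[StallingAssessment]:
    """Quantify zeta for each (or one) non-A residue of a mixed substrate.

    When ``anchor`` is None every non-A residue reachable with the given
    calibration window is assessed separately, control positions taken
    from the matched pure-poly(A) fit at the same absolute positions.
    ``propagate_se`` adds a first-order (delta-method) zeta uncertainty
    from the per-rate standard errors — a diagnostic only; replicate
    s.e.m. is the primary uncertainty report.
    """
    anchors = [anchor] if anchor is not None else substrate.non_a_positions()
    if not anchors:
        raise ValueError(f"substrate {substrate.name} has no non-A residues")
    zm = removal_times(rates_mixed)
    zc = removal_times(rates_control)
    out = []
    for r in anchors:
        base = no_stall_baseline(zm, zc, r, calibration, substrate)
        z = {i: zm.relative(r, i) for i in STALL_WINDOW}
        zeta = stalling_effect(z, base["z_null"])
        se = (
            _zeta_se_delta(rates_mixed, rates_control, r, calibration)
            if propagate_se
            else None
        )
        out.append(
            StallingAssessment(
                substrate=substrate.name,
                anchor=r,
                residue=substrate.residue(r),
                z=z,
                z_null=base["z_null"],
                eps=base["eps"],
                b=base["b"],
                zeta=zeta,
                calibration=calibration,
                zeta_se=se,
            )
        )
    return out


def _zeta_se_delta(rates_mixed, rates_control, anchor, calibration) -> float | None:
    """First-order propagation of per-rate SEs into zeta (diagnostic)."""
    if rates_mixed.se is None or rates_control.se is None:
        return None

    def zeta_of(lam_m, lam_c):
        zm = removal_times(RateProfile(lam_m))
        zc = removal_times(RateProfile(lam_c))
        base = no_stall_baseline(zm, zc, anchor, calibration)
        z = {i: zm.relative(anchor, i) for i in STALL_WINDOW}
        return stalling_effect(z, base["z_null"])

    lam_m, lam_c = rates_mixed.rates, rates_control.rates
    f0 = zeta_of(lam_m, lam_c)
    var = 0.0
    for lam, se in ((lam_m, rates_mixed.se), (lam_c, rates_control.se)):
        for k in range(lam.size):
            if not np.isfinite(se[k]) or se[k] == 0:
                continue
            h = 1e-6 * max(lam[k], 1e-12)
            bumped = lam.copy()
            bumped[k] += h
            if lam is lam_m:
                grad = (zeta_of(bumped, lam_c) - f0) / h
            else:
                grad = (zeta_of(lam_m, bumped) - f0) / h
            var += (grad * se[k]) ** 2
    return float(np.sqrt(var))


def aggregate_replicates(
    assessments: "pd.DataFrame | list",
    by=("residue", "variant"),
) -> pd.DataFrame:
    """Mean and s.e.m. of zeta across replicate fits, per group.

    ``assessments`` is a DataFrame (or list of dicts) with a ``zeta``
    column plus the grouping columns — typically residue type and complex
    variant, with the two residues of a wild-type substrate kept separate
    via an ``anchor`` column.  s.e.m. = sd / sqrt(n) (ddof = 1), reported
    as NaN for n = 1.
    """
    df = pd.DataFrame(assessments)
    if "zeta" not in df.columns:
        raise ValueError("assessments must carry a 'zeta' column")
    by = [c for c in by if c in df.columns]
    if not by:
        raise ValueError("no grouping columns present")
    if df.empty:
        raise ValueError("no replicates to aggregate")

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan

    out = (
        df.groupby(by)["zeta"]
        .agg(mean_zeta="mean", sem_zeta=_sem, n="size")
        .reset_index()
    )
    return out


def effective_tail_length(
    tail_length: int,
    composition: dict[str, int],
    zeta: dict[str, float],
    positions: list[int] | None = None,
) -> tuple[float, float]:
    """Equivalent pure-poly(A) length of a mixed tail, and fold-change.

    Each non-A residue counts as its adenosine-equivalent zeta, so

        effective = (#A) + sum over non-A residues of zeta(residue)

    and fold-change = effective / tail_length.  Interactions between
    closely spaced non-As are not modeled; if ``positions`` (tail
    positions of the non-As) are given and any two lie within 2 nt, a
    warning is raised.
    """
    if tail_length < 1:
        raise ValueError("tail_length must be >= 1")
    counts = {k: int(v) for k, v in composition.items() if k != "A"}
    if any(v < 0 for v in counts.values()):
        raise ValueError("residue counts must be nonnegative")
    n_non_a = sum(counts.values())
    if n_non_a > tail_length:
        raise ValueError("non-A residues exceed the tail length")
    for res, cnt in counts.items():
        if cnt == 0:
            continue
        if res not in zeta:
            raise ValueError(f"no zeta value supplied for residue {res!r}")
        if zeta[res] < 1:
            warnings.warn(
                f"zeta({res}) = {zeta[res]} < 1: a non-A faster than adenosine "
                "is unexpected",
                stacklevel=2,
            )
    if positions is not None:
        pos = sorted(positions)
        if any(b - a <= 2 for a, b in zip(pos, pos[1:])):
            warnings.warn(
                "non-A residues within 2 nt of each other: their interaction "
                "is not modeled, the additive estimate may be off",
                stacklevel=2,
            )
    effective = (tail_length - n_non_a) + sum(
        cnt * zeta[res] for res, cnt in counts.items() if cnt
    )
    return float(effective), float(effective) / tail_length
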