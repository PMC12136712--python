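"""Phage phenotype statistics: efficiency of plating (EOP), host-range
susceptibility counting, thermal/pH stability fold-reductions, and
one-step growth-curve analysis (latent period, burst period, burst size).

Conventions: EOP is a percentage of the reference-host plaque yield;
burst size is the plateau/baseline titer ratio of a triphasic one-step
growth curve (free phage released per infected center); fold-reduction
compares log10 titers before and after an exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ComputationError, ValidationError


@dataclass
class AssayRow:
    """One strain in a host-range assay.

    Either raw replicate plaque counts or a precomputed EOP percentage
    may be supplied (published tables report the latter).
    """

    strain_id: str
    species: str
    spot_result: str  # '+' or '-'
    replicate_pfu: list[float] = field(default_factory=list)
    eop_percent: float | None = None
    is_host: bool = False

    def __post_init__(self) -> None:
        if self.spot_result not in ("+", "-"):
            raise ValidationError("spot_result must be '+' or '-'")
        if any(c < 0 for c in self.replicate_pfu):
            raise ValidationError("plaque counts must be non-negative")


@dataclass
class AssayTable:
    rows: list[AssayRow]

    def __post_init__(self) -> None:
        hosts = [r for r in self.rows if r.is_host]
        if len(hosts) > 1:
            raise ValidationError("host strain flagged more than once")

    @property
    def host(self) -> AssayRow | None:
        for r in self.rows:
            if r.is_host:
                return r
        return None


@dataclass
class GrowthCurve:
    """Titer time series from a one-step growth experiment."""

    times: np.ndarray  # minutes, strictly increasing
    titers: np.ndarray  # PFU/mL, positive

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.asarray(self.titers, dtype=float)
        if self.times.shape != self.titers.shape or self.times.ndim != 1:
            raise ValidationError("times and titers must be equal-length vectors")
        if len(self.times) < 5:
            raise ValidationError("need at least 5 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(self.titers > 0):
            raise ValidationError("titers must be positive")


@dataclass
class StabilitySeries:
    """log10 titers of one condition (a temperature or pH) over exposure."""

    condition: str
    times_min: list[float]
    log10_titers: list[float | None]  # None = below detection limit

    def fold_reductions(
        self, log10_initial: float, detection_limit_log10: float = 0.0
    ) -> list[tuple[float, bool]]:
        """(fold, is_lower_bound) per time point.

        Below-detection points give a lower bound on the reduction,
        computed against the assay detection limit and flagged True.
        """
        out = []
        for v in self.log10_titers:
            if v is None:
                out.append((fold_reduction(log10_initial, detection_limit_log10), True))
            else:
                out.append((fold_reduction(log10_initial, v), False))
        return out


def eop(
    target_counts: list[float], host_counts: list[float]
) -> tuple[float, float]:
    """Efficiency of plating: mean(target)/mean(host) x 100, with SD.

    SD comes from per-replicate ratio pairing when the replicate counts
    line up one-to-one; otherwise from first-order (delta-method) error
    propagation of the two means.
    """
    t = np.asarray(target_counts, dtype=float)
    h = np.asarray(host_counts, dtype=float)
    if len(h) == 0 or h.mean() <= 0:
        raise ValidationError("host mean titer must be positive")
    if len(t) == 0:
        raise ValidationError("no target replicates")
    value = float(t.mean() / h.mean() * 100.0)
    if len(t) == len(h) and len(t) > 1:
        ratios = t / h * 100.0
        sd = float(ratios.std(ddof=1))
    elif len(t) > 1 and len(h) > 1:
        rel_var = t.var(ddof=1) / len(t) / t.mean() ** 2 if t.mean() > 0 else 0.0
        rel_var += h.var(ddof=1) / len(h) / h.mean() ** 2
        sd = float(abs(value) * math.sqrt(rel_var))
    else:
        sd = float("nan")
    return value, sd


def count_susceptible(table: AssayTable, species: str | None = None) -> int:
    """Number of susceptible strains: spot '+' AND EOP > 0.

    A strain can lyse in the spot test yet yield zero plaques in the
    plating assay; such strains are counted as resistant.  ``species``
    restricts the count to rows whose species contains that substring
    (case-insensitive).
    """
    host = table.host
    n = 0
    for r in table.rows:
        if species is not None and species.lower() not in r.species.lower():
            continue
        if r.spot_result != "+":
            continue
        if r.eop_percent is not None:
            e = r.eop_percent
        elif r.replicate_pfu and host is not None and host.replicate_pfu:
            e, _ = eop(r.replicate_pfu, host.replicate_pfu)
        else:
            raise ValidationError(f"row {r.strain_id}: no EOP information")
        if e > 0:
            n += 1
    return n


def fold_reduction(log10_initial: float, log10_final: float) -> float:
    """Titer fold-change 10**(initial - final); > 1 means a decrease."""
    return 10.0 ** (log10_initial - log10_final)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for reporting fold changes)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class GrowthCurveResult:
    latent_min: float
    burst_period: tuple[float, float]
    burst_size: float
    baseline: float
    plateau: float


def growth_curve_analysis(
    curve: GrowthCurve,
    rise_factor: float = 2.0,
    plateau_tolerance: float = 0.10,
    incremental_burst: bool = False,
) -> GrowthCurveResult:
    """Extract latent period, burst period and burst size from a
    triphasic one-step growth curve.

    The baseline is estimated iteratively from the first two points
    outward: a point joins the baseline while its titer stays at or
    below ``rise_factor`` times the running baseline mean.  The latent
    period ends at the last baseline point.  The plateau spans the
    trailing points within ``plateau_tolerance`` of the peak, where the
    peak is robustly taken as the median of the three largest titers so
    one noisy spike cannot shift the threshold.
    Burst size is plateau/baseline (free phage per infected center);
    ``incremental_burst`` switches to (plateau-baseline)/baseline.

    Raises :class:`ComputationError` when no rise is detected.
    """
    t, y = curve.times, curve.titers
    n = len(y)
    baseline_vals = [y[0], y[1]]
    i = 2
    while i < n and y[i] <= rise_factor * np.mean(baseline_vals):
        baseline_vals.append(y[i])
        i += 1
    if i >= n:
        raise ComputationError("no burst detected: curve never rises")
    baseline = float(np.mean(baseline_vals))
    latent = float(t[i - 1])

    # Robust peak: median of the three largest titers (a single noisy
    # spike must not define the plateau threshold).
    peak = float(np.median(np.sort(y)[-3:])) if n >= 3 else float(y.max())
    threshold = (1.0 - plateau_tolerance) * peak
    above = np.nonzero(y[i:] >= threshold)[0]
    if len(above) == 0 or (n - (i + above[0])) < 2:
        raise ComputationError("no burst detected: plateau too short")
    j = i + int(above[0])
    plateau = float(np.mean(y[j:]))
    first_plateau_time = float(t[j])
    burst = plateau / baseline - (1.0 if incremental_burst else 0.0)
    return GrowthCurveResult(
        latent_min=latent,
        burst_period=(latent, first_plateau_time),
        burst_size=float(burst),
        baseline=baseline,
        plateau=plateau,
    )
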