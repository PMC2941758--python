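"""RT-qPCR validation arithmetic.

Three pieces: amplification-efficiency estimation from background-
subtracted fluorescence curves (a log-linear fit over the detected
exponential window), the relative expression ratio (rER) between
with-exon and without-exon transcripts of the same sample, and the
one-tailed unpaired (Welch) t-test used to compare rER values between
sample groups.

The rER for one sample is

    rER = (1 + E_without)^Ct_without / (1 + E_with)^Ct_with

with E the amplification efficiency of each primer pair on the 0-1
scale (perfect doubling has E = 1) and Ct the mean threshold cycle.  No
normalisation gene is involved: the two targets are amplified from the
same cDNA, so their Ct difference is internally controlled.  Computed
in log space, so Ct values up to 50 lose no precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import exp, inf, isfinite, log1p, nan
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_TOL = 0.10      # max spread of cycle-to-cycle log10 ratios
DEFAULT_MIN_WINDOW = 4         # cycles in the exponential window
DEFAULT_MIN_GROWTH = 0.02      # log10 ratio floor (~5%/cycle) vs baseline
DEFAULT_SHOULDER_TOL = 0.04    # trailing ratios this far below the run
                               # maximum belong to the saturation shoulder
DEFAULT_PLATEAU_FRAC = 0.02    # on plateauing curves, fit only below this
                               # fraction of the plateau fluorescence


@dataclass
class AmplificationCurve:
    """One well's background-subtracted fluorescence series."""

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    assay: str = ""       # e.g. with_exon / without_exon
    sample: str = ""

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValueError(f"well {self.well_id}: cycle/fluorescence "
                             f"length mismatch")
        if len(self.cycles) < 10:
            raise ValueError(f"well {self.well_id}: need >= 10 cycles")
        if not np.all(np.diff(self.cycles) > 0):
            raise ValueError(f"well {self.well_id}: cycles must be strictly "
                             f"increasing")


@dataclass
class QpcrAssay:
    """Paired with/without-exon efficiencies and threshold cycles for
    one sample.  Replicate Ct lists, when given, are averaged."""

    sample: str
    E_with: float
    E_without: float
    Ct_with: float = nan
    Ct_without: float = nan
    ct_with_replicates: Sequence[float] = field(default_factory=tuple)
    ct_without_replicates: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("E_with", "E_without"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ct_with_replicates:
            self.Ct_with = float(np.mean(self.ct_with_replicates))
        if self.ct_without_replicates:
            self.Ct_without = float(np.mean(self.ct_without_replicates))

    def swapped(self) -> "QpcrAssay":
        """The assay with with/without labels exchanged."""
        return QpcrAssay(self.sample, self.E_without, self.E_with,
                         self.Ct_without, self.Ct_with)


@dataclass(frozen=True)
class RelativeExpression:
    """An rER value, possibly censored when one target never amplified."""

    value: float
    censored: bool = False
    direction: str | None = None  # ">" (with-exon only) or "<" (without only)


def relative_expression_ratio(assay: QpcrAssay) -> RelativeExpression:
    """rER of with-exon vs without-exon transcripts in one sample.

    A non-finite Ct means the target never crossed threshold; the ratio
    is then censored in the corresponding direction (with-exon
    undetected -> rER below any measurable value, reported 0.0 with
    direction "<"; without-exon undetected -> censored above, inf/">").
    """
    fin_w, fin_wo = isfinite(assay.Ct_with), isfinite(assay.Ct_without)
    if not fin_w and not fin_wo:
        return RelativeExpression(nan, censored=True, direction=None)
    if not fin_w:
        return RelativeExpression(0.0, censored=True, direction="<")
    if not fin_wo:
        return RelativeExpression(inf, censored=True, direction=">")
    log_rer = (assay.Ct_without * log1p(assay.E_without)
               - assay.Ct_with * log1p(assay.E_with))
    return RelativeExpression(exp(log_rer))


def estimate_efficiency(
    curve: AmplificationCurve,
    min_window: int = DEFAULT_MIN_WINDOW,
    tol: float = DEFAULT_WINDOW_TOL,
    min_growth: float = DEFAULT_MIN_GROWTH,
    shoulder_tol: float = DEFAULT_SHOULDER_TOL,
    plateau_frac: float = DEFAULT_PLATEAU_FRAC,
    clip: bool = True,
) -> float:
    """Amplification efficiency E in [0, 1] from one fluorescence curve.

    Detects the exponential window as the longest run of at least
    ``min_window`` cycles whose cycle-to-cycle log10 ratios are
    near-constant (spread <= ``tol``) and all above ``min_growth``
    (which excludes the flat baseline and plateau); trailing cycles
    whose ratio falls more than ``shoulder_tol`` below the run maximum
    are trimmed as the onset of saturation.  log10(fluorescence) is then
    fit against cycle by least squares over the window: E = 10^slope - 1.
    Exact on noise-free geometric series.  Estimates outside [0, 1] are
    clipped with a warning unless ``clip=False``.
    """
    f = curve.fluorescence
    c = curve.cycles
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(f > 0, np.log10(np.where(f > 0, f, 1.0)), np.nan)
    ratios = np.diff(logf) / np.diff(c)
    ok = np.isfinite(ratios) & (ratios >= min_growth)
    # when the curve plateaus (growth has collapsed by the final
    # cycles), amplification stops being exponential well before the
    # plateau: consider only cycles below a small fraction of the
    # plateau fluorescence.  Curves without a plateau are untouched, so
    # noise-free geometric series stay exact.
    finite_ratios = ratios[np.isfinite(ratios)]
    has_plateau = (len(finite_ratios) >= 5
                   and np.median(finite_ratios[-5:]) < min_growth)
    if has_plateau:
        f_cap = plateau_frac * np.nanmax(f)
        f_floor = 1e-3 * f_cap  # at most three decades below the cap,
        ok &= (f[1:] <= f_cap)  # clear of the baseline noise floor
        ok &= (f[1:] >= f_floor) & (f[:-1] >= f_floor)

    # longest contiguous stretch of admissible ratios with spread <= tol
    # (two pointers with monotone deques, O(n))
    from collections import deque

    best: tuple[int, int] | None = None  # (start_ratio_idx, end_ratio_idx)
    n = len(ratios)
    left = 0
    min_q: deque[int] = deque()
    max_q: deque[int] = deque()
    for right in range(n):
        if not ok[right]:
            left = right + 1
            min_q.clear()
            max_q.clear()
            continue
        while min_q and ratios[min_q[-1]] >= ratios[right]:
            min_q.pop()
        min_q.append(right)
        while max_q and ratios[max_q[-1]] <= ratios[right]:
            max_q.pop()
        max_q.append(right)
        while ratios[max_q[0]] - ratios[min_q[0]] > tol:
            left += 1
            if min_q[0] < left:
                min_q.popleft()
            if max_q[0] < left:
                max_q.popleft()
        if best is None or (right - left) > (best[1] - best[0]):
            best = (left, right)

    if best is None or (best[1] - best[0] + 2) < min_window:
        raise ValueError(
            f"well {curve.well_id}: no exponential phase "
            f"(no >= {min_window}-cycle window of near-constant growth)"
        )
    lo_i, hi_i = best
    # trim any saturation shoulder from the tail (ratios well below the
    # run's typical growth), but never below the minimum window
    run_mid = float(np.median(ratios[lo_i:hi_i + 1]))
    while (hi_i - lo_i + 2) > min_window and \
            ratios[hi_i] < run_mid - shoulder_tol:
        hi_i -= 1
    window = slice(lo_i, hi_i + 2)  # ratios i..j involve points i..j+1
    slope = np.polyfit(c[window], logf[window], 1)[0]
    eff = 10.0 ** slope - 1.0
    if not (0.0 <= eff <= 1.0):
        if not clip:
            return float(eff)
        warnings.warn(
            f"well {curve.well_id}: fitted efficiency {eff:.3f} outside "
            f"[0, 1]; clipped", stacklevel=2,
        )
        eff = min(1.0, max(0.0, eff))
    return float(eff)


def one_tailed_unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str = "greater",
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, one-tailed.

    ``direction="greater"`` tests mean(a) > mean(b); ``"less"`` the
    reverse.  Returns (t, df, p).  When both groups have zero variance
    and equal means the test is degenerate; p = 0.5 by convention.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        logger.info("degenerate t-test (zero variance, equal means); p = 0.5")
        df = float(len(a) + len(b) - 2)
        return 0.0, df, 0.5
    res = sps.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.df), float(res.pvalue)


def simulate_curve(
    efficiency: float,
    rng: np.random.Generator,
    n_cycles: int = 50,
    f0: float = 1e-7,
    plateau: float = 1.0,
    noise_sd: float = 0.02,
    baseline_sd: float = 1e-6,
    well_id: str = "sim",
) -> AmplificationCurve:
    """A plausible background-subtracted qPCR curve for testing.

    Exponential growth ``f0 * (1+E)^cycle`` saturating towards
    ``plateau``, with multiplicative log-normal noise (sd ``noise_sd``)
    and an additive baseline noise floor that masks the earliest cycles,
    as residual background subtraction does in real runs.  Defaults
    mirror a 50-cycle run spanning ~7 logs of amplification from
    threshold-level template.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    ideal = f0 * (1.0 + efficiency) ** cycles
    sat = ideal / (1.0 + ideal / plateau)
    noisy = sat * np.exp(rng.normal(0.0, noise_sd, size=n_cycles))
    noisy = noisy + rng.normal(0.0, baseline_sd, size=n_cycles)
    return AmplificationCurve(well_id, cycles, np.maximum(noisy, 1e-12))
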