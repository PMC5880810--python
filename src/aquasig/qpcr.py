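"""RT-qPCR relative quantification.

The chain implemented here follows standard relative-quantification
practice: per-well amplification efficiency from the best log-linear
window of the exponential phase (LinRegPCR-style), quantification-cycle
(Cq) calling by threshold crossing, exclusion of samples whose noRT
control amplifies fewer than five cycles after the sample, geNorm
reference-gene stability ranking, calibrated normalized relative
quantities (CNRQ, qBase convention with the per-target mean Cq as
calibrator), and the Brown-Forsythe robust equality-of-means test with
Scheffe post hoc contrasts on log-transformed CNRQs.

Censoring (no threshold crossing, missing reference Cq) propagates and
is never imputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError
from .synth import WellRecord

NOISE_BAND_SD_FACTOR = 10.0
BASELINE_CYCLES = 5
DEFAULT_WINDOW_LENS = (4, 5, 6)
MIN_WINDOW_R2 = 0.99
DEFAULT_CQ_FACTOR = 10.0
DEFAULT_MIN_DELTA = 5.0


def _baseline_and_noise_band(f: np.ndarray) -> tuple[float, float]:
    head = f[:BASELINE_CYCLES]
    return float(head.mean()), float(head.mean() + NOISE_BAND_SD_FACTOR * head.std(ddof=0))


# ---------------------------------------------------------------------------
# Efficiency estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellEfficiency:
    sample: str
    efficiency: float | None
    window: tuple[int, int] | None    # (start cycle, length)
    r2: float | None
    flagged: bool
    reason: str | None


@dataclass(frozen=True)
class EfficiencyEstimate:
    target: str
    efficiency: float                 # arithmetic mean over usable wells
    wells: tuple[WellEfficiency, ...]

    @property
    def n_wells(self) -> int:
        return sum(1 for w in self.wells if w.efficiency is not None)


def _well_efficiency(well: WellRecord,
                     window_lens: tuple[int, ...]) -> WellEfficiency:
    f = np.asarray(well.fluorescence, dtype=float)
    baseline, noise_band = _baseline_and_noise_band(f)
    plateau = float(f.max())
    phase = np.flatnonzero((f >= noise_band) & (f <= plateau / 2.0))

    def window_fit(idx: np.ndarray, b: float) -> tuple[float, float]:
        fit = stats.linregress(idx + 1.0, np.log10(f[idx] - b))
        return fit.rvalue ** 2, fit.slope

    best = None
    usable = phase[f[phase] - baseline > 0]
    for length in window_lens:
        for s in range(len(usable) - length + 1):
            idx = usable[s:s + length]
            if idx[-1] - idx[0] != length - 1:       # must be contiguous cycles
                continue
            r2, slope = window_fit(idx, baseline)
            if best is None or r2 > best[0]:
                best = (r2, slope, idx)
    if best is None:
        return WellEfficiency(well.sample, None, None, None, True,
                              "no exponential phase")
    # refine the baseline on the chosen window: the subtraction that
    # maximises log-linearity (handles curves already exponential at
    # cycle 1, where the early-cycle mean contains signal)
    _, _, idx = best
    upper = float(f[idx].min()) * 0.999
    res = optimize.minimize_scalar(
        lambda b: -window_fit(idx, b)[0], bounds=(0.0, max(upper, 1e-12)),
        method="bounded")
    r2_ref, slope_ref = window_fit(idx, float(res.x))
    r2, slope = best[0], best[1]
    if r2_ref > r2:
        r2, slope = r2_ref, slope_ref
    eff = 10.0 ** slope
    return WellEfficiency(well.sample, float(eff),
                          (int(idx[0] + 1), len(idx)), float(r2),
                          r2 < MIN_WINDOW_R2, None)


def estimate_efficiency(wells: list[WellRecord],
                        window_lens: tuple[int, ...] = DEFAULT_WINDOW_LENS
                        ) -> EfficiencyEstimate:
    """Target-level amplification efficiency from its sample wells.

    Per well, the contiguous window (length 4-6 by default) inside the
    exponential phase — readings above the noise band (mean + 10 SD of
    cycles 1-5) and below half the plateau — that maximises the R^2 of
    log10(fluorescence - baseline) vs cycle defines E = 10^slope.
    The target estimate is the arithmetic mean over usable wells.
    """
    sample_wells = [w for w in wells if w.well_type == "sample"]
    if not sample_wells:
        raise AnalysisError("no sample wells for efficiency estimation")
    target = sample_wells[0].target
    per_well = tuple(_well_efficiency(w, window_lens) for w in sample_wells)
    values = [w.efficiency for w in per_well if w.efficiency is not None]
    if not values:
        raise AnalysisError(f"target {target}: all wells excluded "
                            "(no exponential phase)")
    return EfficiencyEstimate(target=target, efficiency=float(np.mean(values)),
                              wells=per_well)


# ---------------------------------------------------------------------------
# Cq calling and noRT exclusion
# ---------------------------------------------------------------------------

def compute_cq(well: WellRecord, threshold: float | None = None,
               factor: float = DEFAULT_CQ_FACTOR) -> float | None:
    """Fractional cycle at which fluorescence first crosses the threshold.

    The default threshold sits a fixed factor (10x) above the noise band;
    the crossing is located by log-linear interpolation between the
    bracketing cycles.  Returns None (censored) when the curve never
    crosses.
    """
    f = np.asarray(well.fluorescence, dtype=float)
    if threshold is None:
        _, noise_band = _baseline_and_noise_band(f)
        threshold = factor * max(noise_band, 1e-12)
    above = np.flatnonzero(f >= threshold)
    if len(above) == 0:
        return None
    c = int(above[0])
    if c == 0:
        return 1.0
    f0, f1 = max(f[c - 1], 1e-12), f[c]
    if f1 <= f0:
        return float(c + 1)
    frac = (math.log(threshold) - math.log(f0)) / (math.log(f1) - math.log(f0))
    return float(c + frac)           # cycles are 1-based: c == cycle c+1's index


@dataclass(frozen=True)
class NoRtDecision:
    keep: bool
    delta: float | None
    reason: str


def filter_noRT(sample_cq: float | None, noRT_cq: float | None,
                min_delta: float = DEFAULT_MIN_DELTA) -> NoRtDecision:
    """Drop a sample when its noRT control amplifies < ``min_delta``
    cycles after it (genomic DNA contamination); a censored noRT
    (no amplification) keeps the sample."""
    if sample_cq is None:
        return NoRtDecision(False, None, "sample Cq missing")
    if noRT_cq is None:
        return NoRtDecision(True, None, "noRT censored (no amplification)")
    delta = noRT_cq - sample_cq
    if delta < min_delta:
        return NoRtDecision(False, delta,
                            f"noRT - sample Cq = {delta:.2f} < {min_delta:g}")
    return NoRtDecision(True, delta, "ok")


# ---------------------------------------------------------------------------
# geNorm reference stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityRanking:
    m_values: dict[str, float]        # initial M per candidate
    exclusion_order: tuple[str, ...]  # least stable first
    selected_pair: tuple[str, str]


def _log2_rq(cq_table: pd.DataFrame, efficiencies: dict[str, float]
             ) -> pd.DataFrame:
    out = {}
    for target in cq_table.columns:
        e = efficiencies[target]
        cq = cq_table[target].astype(float)
        out[target] = math.log2(e) * (cq.mean() - cq)
    return pd.DataFrame(out, index=cq_table.index)


def genorm_stability(cq_table: pd.DataFrame,
                     efficiencies: dict[str, float]) -> StabilityRanking:
    """Classic geNorm: M_j = mean over other candidates k of the SD
    across samples of log2(RQ_j / RQ_k); the highest-M candidate is
    dropped iteratively until two remain.

    ``cq_table`` is samples x candidate-targets, complete-case: a
    missing value raises, naming the candidate.
    """
    if cq_table.shape[1] < 3:
        raise AnalysisError("geNorm needs at least 3 candidate references")
    if cq_table.shape[0] < 2:
        raise AnalysisError("geNorm needs at least 2 samples")
    for cand in cq_table.columns:
        if cq_table[cand].isna().any():
            raise AnalysisError(f"candidate {cand!r} has missing sample values")
    log_rq = _log2_rq(cq_table, efficiencies)

    def m_values(cols: list[str]) -> dict[str, float]:
        out = {}
        for j in cols:
            sds = [float((log_rq[j] - log_rq[k]).std(ddof=1))
                   for k in cols if k != j]
            out[j] = float(np.mean(sds))
        return out

    remaining = list(cq_table.columns)
    initial = m_values(remaining)
    excluded: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        # ties broken by input order: the later candidate is dropped first
        worst = max(remaining, key=lambda c: (round(m[c], 12),
                                              remaining.index(c)))
        excluded.append(worst)
        remaining.remove(worst)
    return StabilityRanking(m_values=initial,
                            exclusion_order=tuple(excluded),
                            selected_pair=(remaining[0], remaining[1]))


# ---------------------------------------------------------------------------
# CNRQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnrqTable:
    """Per-(sample, target) relative quantities with provenance."""

    table: pd.DataFrame               # columns: sample, target, cq, rq, nrq, cnrq
    reference_targets: tuple[str, ...]
    efficiencies: dict[str, float]
    calibration: dict[str, float]     # per-target geometric mean of NRQ

    def cnrq(self, sample: str, target: str) -> float:
        row = self.table[(self.table["sample"] == sample)
                         & (self.table["target"] == target)]
        return float(row["cnrq"].iloc[0])


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def compute_cnrq(cq_table: pd.DataFrame, efficiencies: dict[str, float],
                 reference_targets: tuple[str, ...] | list[str]) -> CnrqTable:
    """Calibrated normalized relative quantities.

    RQ_{s,t} = E_t^(mean_s Cq_t - Cq_{s,t});
    NRQ = RQ / geometric mean of the reference-target RQs of the sample;
    CNRQ = NRQ / geometric mean of NRQ over samples (per target), so the
    per-target geometric mean of CNRQ is exactly 1.

    ``cq_table`` is long-form with columns sample, target, cq (NaN =
    censored).  Samples missing any reference Cq get censored NRQ/CNRQ.
    """
    reference_targets = tuple(reference_targets)
    if not reference_targets:
        raise AnalysisError("at least one reference target is required")
    wide = cq_table.pivot_table(index="sample", columns="target", values="cq",
                                dropna=False)
    for t in reference_targets:
        if t not in wide.columns:
            raise AnalysisError(f"reference target {t!r} missing from Cq table")
    missing = {t for t in set(cq_table["target"]) if t not in efficiencies}
    if missing:
        raise AnalysisError(f"no efficiency for target(s) {sorted(missing)}")

    rq = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for t in wide.columns:
        cq = wide[t].astype(float)
        rq[t] = efficiencies[t] ** (cq.mean(skipna=True) - cq)
    ref_ok = wide[list(reference_targets)].notna().all(axis=1)
    norm = np.exp(np.log(rq[list(reference_targets)]).mean(axis=1))
    norm[~ref_ok] = np.nan
    nrq = rq.div(norm, axis=0)
    calibration = {}
    cnrq = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for t in wide.columns:
        vals = nrq[t].dropna()
        cal = _geomean(vals.to_numpy()) if len(vals) else np.nan
        calibration[t] = float(cal)
        cnrq[t] = nrq[t] / cal

    long = (pd.concat({"cq": wide, "rq": rq, "nrq": nrq, "cnrq": cnrq}, axis=1)
            .stack(future_stack=True).reset_index())
    long.columns = ["sample", "target", "cq", "rq", "nrq", "cnrq"]
    return CnrqTable(table=long, reference_targets=reference_targets,
                     efficiencies=dict(efficiencies), calibration=calibration)


# ---------------------------------------------------------------------------
# Robust group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrownForsytheResult:
    f_star: float
    df1: float
    df2: float
    p_value: float


def brown_forsythe(groups: list[np.ndarray | list[float]]) -> BrownForsytheResult:
    """Brown-Forsythe robust test of equality of means.

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with
    Satterthwaite-type denominator degrees of freedom.  With equal group
    sizes F* reduces to the classic one-way ANOVA F.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise AnalysisError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise AnalysisError("every group needs n >= 2")
    n = np.array([len(a) for a in arrays], dtype=float)
    N = n.sum()
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    grand = float((n * means).sum() / N)
    num = float((n * (means - grand) ** 2).sum())
    weights = (1.0 - n / N) * variances
    den = float(weights.sum())
    if den == 0.0:
        f_star = 0.0 if num == 0.0 else math.inf
    else:
        f_star = num / den
    df1 = len(arrays) - 1
    if den == 0.0:
        df2 = float(N - len(arrays))
    else:
        c = weights / den
        df2 = 1.0 / float((c ** 2 / (n - 1)).sum())
    p = float(stats.f.sf(f_star, df1, df2)) if math.isfinite(f_star) else 0.0
    if f_star == 0.0:
        p = 1.0
    return BrownForsytheResult(float(f_star), float(df1), float(df2), p)


def brown_forsythe_fstar(samples: np.ndarray) -> np.ndarray:
    """Vectorised F* over many replicates of an equal-n design.

    ``samples`` has shape (reps, k, n); returns shape (reps,).  The
    Satterthwaite df2 per replicate is returned by
    :func:`brown_forsythe_df2`.
    """
    reps, k, n = samples.shape
    means = samples.mean(axis=2)
    variances = samples.var(axis=2, ddof=1)
    grand = means.mean(axis=1)
    num = n * ((means - grand[:, None]) ** 2).sum(axis=1)
    den = (1.0 - 1.0 / k) * variances.sum(axis=1)
    return num / den


def brown_forsythe_df2(samples: np.ndarray) -> np.ndarray:
    reps, k, n = samples.shape
    variances = samples.var(axis=2, ddof=1)
    weights = (1.0 - 1.0 / k) * variances
    c = weights / weights.sum(axis=1, keepdims=True)
    return 1.0 / ((c ** 2).sum(axis=1) / (n - 1))


@dataclass(frozen=True)
class ScheffeComparison:
    pair: tuple[int, int]
    contrast: float
    f_pair: float
    critical: float
    significant: bool


def scheffe_posthoc(groups: list[np.ndarray | list[float]],
                    alpha: float = 0.05) -> list[ScheffeComparison]:
    """Scheffe post hoc pairwise contrasts after a one-way design.

    A pair is significant when its contrast F exceeds
    (k - 1) * F_crit(alpha; k - 1, N - k); conservative for all pairwise
    comparisons by construction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise AnalysisError("need >= 2 groups with n >= 2 each")
    k = len(arrays)
    n = np.array([len(a) for a in arrays], dtype=float)
    N = n.sum()
    msw = float(sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / (N - k))
    f_crit = float(stats.f.isf(alpha, k - 1, N - k))
    critical = (k - 1) * f_crit
    out = []
    for i, j in itertools.combinations(range(k), 2):
        contrast = float(arrays[i].mean() - arrays[j].mean())
        if msw == 0.0:
            f_pair = 0.0 if contrast == 0.0 else math.inf
        else:
            f_pair = contrast ** 2 / (msw * (1.0 / n[i] + 1.0 / n[j]))
        out.append(ScheffeComparison((i, j), contrast, float(f_pair),
                                     critical, bool(f_pair > critical)))
    return out
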