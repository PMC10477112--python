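"""Group statistics: ROUT outlier removal, Student's t, fold changes, ΔΔCT, LOD.

The outlier step follows the ROUT idea — a robust fit with a Lorentzian merit
function, a robust standard deviation of the residuals (RSDR) from the 68.27th
percentile, and an FDR-controlled sweep over the most extreme residuals —
specialized here to a location-only model, since the quantities being cleaned
are univariate per-image measurements. All constants (the 68.27 percentile,
the n/(n-K) small-sample correction, the largest-residual-first
Benjamini–Hochberg gate) are fixed and documented in the docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, ParameterError, ValidationError


@dataclass
class MeasurementSample:
    """A labeled sample of real measurements (one per image or differentiation)."""

    values: np.ndarray
    group_label: str = ""
    unit: str = "image"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("values must be a flat sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class RoutResult:
    """Outcome of ROUT outlier removal on one sample."""

    kept: np.ndarray
    outlier_indices: np.ndarray
    q: float
    robust_center: float
    rsdr: float

    @property
    def n_outliers(self) -> int:
        return self.outlier_indices.size


@dataclass
class ComparisonResult:
    """Two-sample comparison: means ± SEM, fold change, pooled-variance t."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change_b_vs_a: float
    t_statistic: float
    p_value: float
    df: int
    n_a: int
    n_b: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        """Two-tailed p below the 0.05 significance level."""
        return self.p_value < 0.05


@dataclass
class QpcrSample:
    """One qPCR sample: target CT plus one or more reference-gene CTs.

    Technical duplicates may be passed as sequences; they are averaged first.
    """

    ct_target: float | Sequence[float]
    ct_refs: Sequence[float | Sequence[float]]
    sample_label: str = ""
    calibrator: bool = False

    def mean_ct_target(self) -> float:
        return float(np.mean(np.atleast_1d(np.asarray(self.ct_target, dtype=float))))

    def mean_ct_ref(self) -> float:
        if len(self.ct_refs) == 0:
            raise ValidationError(
                f"sample {self.sample_label!r}: at least one reference CT required"
            )
        per_gene = [float(np.mean(np.atleast_1d(np.asarray(c, dtype=float))))
                    for c in self.ct_refs]
        return float(np.mean(per_gene))

    def delta_ct(self) -> float:
        target, ref = self.mean_ct_target(), self.mean_ct_ref()
        if target <= 0 or ref <= 0:
            raise ValidationError("CT values must be positive")
        return target - ref


def _robust_location(values: np.ndarray, max_iter: int = 200,
                     tol: float = 1e-12) -> tuple[float, float]:
    """Iteratively reweighted location fit with Lorentzian weights.

    Minimizes sum(log(1 + (r_i / s)^2)) over the center, re-estimating the
    scale s as RSDR = P68.27(|r|) * n/(n-1) each iteration (K = 1 fitted
    parameter). Returns (center, rsdr).
    """
    n = values.size
    center = float(np.median(values))
    scale_ref = float(np.max(np.abs(values - center))) or 1.0

    def rsdr_of(res: np.ndarray) -> float:
        return float(np.percentile(np.abs(res), 68.27)) * n / (n - 1)

    rsdr = rsdr_of(values - center)
    for _ in range(max_iter):
        res = values - center
        if rsdr == 0.0:
            break
        w = 1.0 / (1.0 + (res / rsdr) ** 2)
        new_center = float(np.sum(w * values) / np.sum(w))
        rsdr = rsdr_of(values - new_center)
        if abs(new_center - center) <= tol * scale_ref:
            center = new_center
            break
        center = new_center
    return center, rsdr


def rout_outliers(sample: MeasurementSample | Sequence[float],
                  q: float = 0.001) -> RoutResult:
    """Flag definite outliers with the ROUT procedure at FDR level ``q``.

    Location-only specialization: the robust center plays the role of the
    robust fit. Each point gets a two-tailed tail probability from
    ``t = |residual| / RSDR`` on a Student t distribution with ``n - 1``
    degrees of freedom; candidates are swept most-extreme-first through a
    Benjamini–Hochberg gate at level ``q`` (equivalently, the i-th ranked
    residual is tested against ``alpha_i = q * (n - i + 1) / n``). At most
    ``n // 2`` points can ever be removed.

    The published default, Q = 0.1 %, removes only definite outliers.
    """
    if isinstance(sample, MeasurementSample):
        values = sample.values
    else:
        values = MeasurementSample(np.asarray(sample, dtype=float)).values
    if not 0 < q < 1:
        raise ParameterError(f"Q must be in (0, 1), got {q}")
    n = values.size
    if n < 3:
        raise InsufficientDataError(f"ROUT needs n >= 3, got n = {n}")

    center, rsdr = _robust_location(values)
    residuals = values - center
    if rsdr == 0.0:  # constant (or majority-constant) data: nothing to flag
        return RoutResult(kept=values.copy(),
                          outlier_indices=np.empty(0, dtype=int),
                          q=q, robust_center=center, rsdr=0.0)

    order = np.argsort(-np.abs(residuals), kind="stable")  # most extreme first
    tvals = np.abs(residuals[order]) / rsdr
    pvals = 2.0 * sps.t.sf(tvals, df=n - 1)

    cap = n // 2
    ks = np.arange(1, cap + 1)
    passed = pvals[:cap] <= q * ks / n
    n_out = int(ks[passed][-1]) if passed.any() else 0

    outlier_idx = np.sort(order[:n_out])
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[outlier_idx] = False
    return RoutResult(kept=values[keep_mask], outlier_indices=outlier_idx,
                      q=q, robust_center=center, rsdr=rsdr)


def t_test_two_tailed(a: MeasurementSample | Sequence[float],
                      b: MeasurementSample | Sequence[float],
                      welch: bool = False) -> ComparisonResult:
    """Student's two-tailed t test (pooled variance; Welch behind a flag).

    Degenerate conventions: zero pooled variance with equal means gives
    ``t = 0, p = 1``; zero variance with different means gives ``p = 0``
    with the ``degenerate`` flag set.
    """
    va = a.values if isinstance(a, MeasurementSample) else np.asarray(a, float)
    vb = b.values if isinstance(b, MeasurementSample) else np.asarray(b, float)
    na, nb = va.size, vb.size
    if na < 2 or nb < 2:
        raise InsufficientDataError("t test needs n >= 2 in both groups")

    mean_a, mean_b = float(va.mean()), float(vb.mean())
    var_a, var_b = float(va.var(ddof=1)), float(vb.var(ddof=1))
    sem_a = float(np.sqrt(var_a / na))
    sem_b = float(np.sqrt(var_b / nb))
    fold = mean_b / mean_a if mean_a != 0 else float("nan")

    if welch:
        se2 = var_a / na + var_b / nb
        if se2 == 0.0:
            return _degenerate_comparison(mean_a, mean_b, sem_a, sem_b, fold,
                                          na, nb, df=na + nb - 2)
        t_stat = (mean_a - mean_b) / np.sqrt(se2)
        df_w = se2 ** 2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
        p = float(2.0 * sps.t.sf(abs(t_stat), df=df_w))
        return ComparisonResult(mean_a, mean_b, sem_a, sem_b, fold,
                                float(t_stat), p, int(round(df_w)), na, nb)

    df = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
    if pooled == 0.0:
        return _degenerate_comparison(mean_a, mean_b, sem_a, sem_b, fold,
                                      na, nb, df=df)
    t_stat = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = float(2.0 * sps.t.sf(abs(t_stat), df=df))
    return ComparisonResult(mean_a, mean_b, sem_a, sem_b, fold,
                            float(t_stat), p, df, na, nb)


def _degenerate_comparison(mean_a, mean_b, sem_a, sem_b, fold,
                           na, nb, df) -> ComparisonResult:
    if mean_a == mean_b:
        return ComparisonResult(mean_a, mean_b, sem_a, sem_b, fold,
                                0.0, 1.0, df, na, nb)
    t_stat = float(np.inf) if mean_a > mean_b else float(-np.inf)
    return ComparisonResult(mean_a, mean_b, sem_a, sem_b, fold,
                            t_stat, 0.0, df, na, nb, degenerate=True)


@dataclass
class FoldChangeResult:
    """Per-value and mean fold changes with the first sample as calibrator."""

    per_value_calibrator: np.ndarray
    per_value_other: np.ndarray
    mean_fold_other_vs_calibrator: float


def fold_change_vs_calibrator(a: MeasurementSample | Sequence[float],
                              b: MeasurementSample | Sequence[float]) -> FoldChangeResult:
    """Express every value relative to the calibrator-group mean (set to 1)."""
    va = a.values if isinstance(a, MeasurementSample) else np.asarray(a, float)
    vb = b.values if isinstance(b, MeasurementSample) else np.asarray(b, float)
    mean_a = float(va.mean())
    if mean_a == 0.0:
        raise ParameterError("calibrator mean is zero: fold change undefined")
    folds_a, folds_b = va / mean_a, vb / mean_a
    return FoldChangeResult(folds_a, folds_b, float(folds_b.mean()))


def delta_delta_ct(samples: Sequence[QpcrSample]):
    """Relative expression by the ΔΔCT rule with a calibrator group.

    ΔCT = CT_target − mean(CT_refs); ΔΔCT = ΔCT − mean ΔCT of calibrator
    samples; RQ = 2^(−ΔΔCT). The calibrator group's mean ΔΔCT is 0, so its
    RQ is 1 by construction. Returns a pandas DataFrame with one row per
    sample (label, delta_ct, delta_delta_ct, rq, calibrator flag).
    """
    import pandas as pd

    if not samples:
        raise ValidationError("no qPCR samples provided")
    dcts = np.array([s.delta_ct() for s in samples])
    cal = np.array([s.calibrator for s in samples], dtype=bool)
    if not cal.any():
        raise ValidationError("exactly one calibrator group required; none flagged")
    dct_cal = float(dcts[cal].mean())
    ddct = dcts - dct_cal
    return pd.DataFrame({
        "sample_label": [s.sample_label for s in samples],
        "delta_ct": dcts,
        "delta_delta_ct": ddct,
        "rq": np.power(2.0, -ddct),
        "calibrator": cal,
    })


def censor_below_lod(values: Sequence[float], lod: float) -> tuple[np.ndarray, int]:
    """Replace measurements strictly below the detection limit by LOD/2.

    Values exactly at the LOD are unchanged. Returns the censored array and
    the number of values replaced.
    """
    if lod <= 0:
        raise ParameterError(f"LOD must be positive, got {lod}")
    arr = np.asarray(values, dtype=np.float64).copy()
    below = arr < lod
    arr[below] = lod / 2.0
    return arr, int(below.sum())
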