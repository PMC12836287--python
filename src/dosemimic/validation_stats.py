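"""Leave-one-out validation and the nonparametric statistics harness.

Predictor validation is leave-one-out cross-validation: each cohort
case is predicted from an atlas built on the remaining cases, and the
geometric accuracy of the predicted low-dose volume is scored with the
Dice similarity coefficient of the 2-Gy isodose against the case's
actual dose.

The comparison harness mirrors standard small-cohort plan-comparison
practice: Fisher's exact test for categorical baseline variables,
Mann-Whitney U for independent continuous comparisons, Friedman across
paired plan arms with Wilcoxon signed-rank post-hoc tests, and a
step-down Holm-Bonferroni family-wise correction (implemented here
directly).  Fisher's exact two-sided p-value is computed by explicit
hypergeometric enumeration using the point-probability rule: the sum of
probabilities of all tables (at fixed margins) no more likely than the
observed one.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_prediction import build_atlas, predict_dose
from .block_generation import extract_isodose
from .dosimetry_eval import dice
from .registration import RegistrationConfig
from .volumes_io import PatientCase

__all__ = [
    "LooCaseResult",
    "LooResult",
    "leave_one_out",
    "fisher_exact",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman",
    "holm_bonferroni",
    "build_comparison_table",
    "Contrast",
]


# ---------------------------------------------------------------------------
# leave-one-out validation
# ---------------------------------------------------------------------------

@dataclass
class LooCaseResult:
    id: str
    dsc_2gy: float
    mean_abs_error_gy: float
    wall_time_s: float


@dataclass
class LooResult:
    cases: list[LooCaseResult]
    mean_dsc: float
    sd_dsc: float
    failures: list[str] = dc_field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": c.id,
                    "dsc_2gy": c.dsc_2gy,
                    "mean_abs_error_gy": c.mean_abs_error_gy,
                    "wall_time_s": c.wall_time_s,
                }
                for c in self.cases
            ]
        )


def leave_one_out(
    cases: list[PatientCase],
    config: RegistrationConfig | None = None,
    reference_id: str | None = None,
    threshold_gy: float = 2.0,
    p: float = 1.0,
) -> LooResult:
    """Leave-one-out cross-validation of the atlas dose predictor.

    For every case, an atlas is built from the remaining cases (using
    the pinned ``reference_id`` when it is among them, otherwise the
    first remaining case in id order), the held-out case's dose is
    predicted, and the Dice coefficient of the ``threshold_gy`` isodose
    against the actual dose is recorded together with the mean absolute
    dose error over the body.

    Registration results are memoized across folds: the predictor is
    deterministic, so re-registering an unchanged (reference, member)
    pair would reproduce the identical field.
    """
    if len(cases) < 3:
        raise ValueError("leave-one-out needs at least 3 cases")
    config = config or RegistrationConfig()
    reg_cache: dict = {}
    results: list[LooCaseResult] = []
    failures: list[str] = []
    for held in cases:
        rest = [c for c in cases if c.id != held.id]
        if reference_id is not None and any(c.id == reference_id for c in rest):
            ref_id = reference_id
        else:
            ref_id = min(c.id for c in rest)
        t0 = time.perf_counter()
        try:
            atlas = build_atlas(rest, ref_id, config, reg_cache=reg_cache)
            pred = predict_dose(atlas, held, p=p, reg_cache=reg_cache)
        except Exception as exc:
            warnings.warn(f"LOO fold for {held.id!r} failed: {exc}")
            failures.append(held.id)
            continue
        elapsed = time.perf_counter() - t0
        d = dice(
            extract_isodose(pred.predicted_dose, threshold_gy),
            extract_isodose(held.dose, threshold_gy),
        )
        body = held.structures["Body"].values
        mae = float(
            np.abs(pred.predicted_dose.values - held.dose.values)[body].mean()
        )
        results.append(LooCaseResult(held.id, d, mae, elapsed))
    if not results:
        raise RuntimeError("every leave-one-out fold failed")
    dscs = np.array([r.dsc_2gy for r in results])
    return LooResult(
        cases=results,
        mean_dsc=float(dscs.mean()),
        sd_dsc=float(dscs.std(ddof=1)) if dscs.size > 1 else 0.0,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Enumerates the hypergeometric distribution at fixed margins and sums
    the probabilities of all tables whose point probability does not
    exceed the observed one (with a small relative guard against
    floating-point ties).  A zero margin returns p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    a = int(t[0, 0])
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    n = int(t.sum())
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn("degenerate margin in contingency table; p = 1")
        return 1.0
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    observed = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return min(p, 1.0)


def mann_whitney_u(x, y) -> tuple[float, float, str]:
    """Mann-Whitney U with two-sided p.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise; returns ``(U, p, method)``.  Two samples with
    every value identical give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return float(x.size * y.size / 2.0), 1.0, "degenerate"
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact_ok = not has_ties and max(x.size, y.size) <= 25
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float, str]:
    """Wilcoxon signed-rank test (paired), zero differences dropped.

    Exact p for n <= 25 (sign-flip enumeration over the signed-rank
    distribution, valid with tied |differences|), normal approximation
    otherwise; returns ``(W, p, method)``.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, "degenerate"
    if d.size <= 25:
        return (*_exact_signed_rank(d), "exact")
    res = stats.wilcoxon(d, method="approx")
    return float(res.statistic), float(res.pvalue), "approx"


def _exact_signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by dynamic programming.

    Average ranks of |d| are doubled to integers; the distribution of
    the positive-rank sum under the 2^n equiprobable sign flips is the
    coefficient sequence of ``prod_i (1 + x^{2 r_i})``.
    """
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    doubled = np.rint(2 * ranks).astype(int)
    counts = np.zeros(doubled.sum() + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    total = counts.sum()  # 2^n
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / total
    sf = counts[w2:].sum() / total
    p = min(1.0, 2.0 * min(cdf, sf))
    w_stat = min(w_plus, float(ranks.sum()) - w_plus)
    return w_stat, p


def friedman(matrix) -> tuple[float, float]:
    """Friedman test on a subjects x conditions matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if np.all(m == m[:, :1]):  # all conditions identical per subject
        return 0.0, 1.0
    if m.shape[1] == 2:
        # scipy requires >= 3 conditions; fall back to the sign structure
        stat, p, _ = wilcoxon_signed_rank(m[:, 0], m[:, 1])
        return stat, p
    res = stats.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(
    pvalues, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni correction.

    Sorts the m p-values ascending and rejects sequentially while
    ``p_(k) <= alpha / (m - k + 1)``; the adjusted p-value is the
    running maximum of ``(m - k + 1) * p_(k)`` capped at 1.  Returns
    ``(adjusted_p, reject)`` in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    running = 0.0
    still_rejecting = True
    for k, idx in enumerate(order):
        factor = m - k
        running = max(running, min(1.0, factor * p[idx]))
        adjusted[idx] = running
        if still_rejecting and p[idx] <= alpha / factor:
            reject[idx] = True
        else:
            still_rejecting = False
    return adjusted, reject


# ---------------------------------------------------------------------------
# cohort comparison tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """A planned comparison between two cohort arms.

    ``paired`` arms share subjects (row-aligned tables); unpaired arms
    are independent cohorts.
    """

    name: str
    arm_a: str
    arm_b: str
    paired: bool = False


def build_comparison_table(
    cohorts: dict[str, pd.DataFrame],
    contrasts: list[Contrast],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean ± SD per arm and corrected p-values per planned contrast.

    ``cohorts`` maps arm name to a cases x metrics table.  Independent
    contrasts use Mann-Whitney U.  Paired contrasts are gated, per
    metric, by a Friedman test across every arm involved in a paired
    contrast; the pairwise Wilcoxon signed-rank p-values are then
    Holm-Bonferroni corrected within the metric family.  Contrasts are
    declared up front (no data-dependent test selection).
    """
    if not contrasts:
        raise ValueError("declare at least one contrast")
    metrics = list(next(iter(cohorts.values())).columns)
    for arm, df in cohorts.items():
        if list(df.columns) != metrics:
            raise ValueError(f"arm {arm!r} has mismatched metric columns")
    paired_arms = sorted(
        {c.arm_a for c in contrasts if c.paired}
        | {c.arm_b for c in contrasts if c.paired}
    )
    if paired_arms:
        n_rows = {len(cohorts[a]) for a in paired_arms}
        if len(n_rows) != 1:
            raise ValueError("paired arms must have identical subject counts")

    rows = []
    for metric in metrics:
        row: dict = {"metric": metric}
        for arm, df in cohorts.items():
            v = df[metric].to_numpy(dtype=float)
            row[f"{arm}_mean"] = v.mean()
            row[f"{arm}_sd"] = v.std(ddof=1) if v.size > 1 else 0.0
        friedman_p = None
        if len(paired_arms) >= 2:
            mat = np.column_stack(
                [cohorts[a][metric].to_numpy(dtype=float) for a in paired_arms]
            )
            _, friedman_p = friedman(mat)
            row["friedman_p"] = friedman_p
        raw_paired: list[tuple[Contrast, float, str]] = []
        for c in contrasts:
            va = cohorts[c.arm_a][metric].to_numpy(dtype=float)
            vb = cohorts[c.arm_b][metric].to_numpy(dtype=float)
            if c.paired:
                stat, pval, method = wilcoxon_signed_rank(va, vb)
                raw_paired.append((c, pval, f"wilcoxon[{method}]"))
            else:
                stat, pval, method = mann_whitney_u(va, vb)
                row[f"p_{c.name}"] = pval
                row[f"test_{c.name}"] = f"mann-whitney[{method}]"
        if raw_paired:
            adj, rej = holm_bonferroni([p for _, p, _ in raw_paired], alpha)
            for (c, pval, label), ap, rj in zip(raw_paired, adj, rej):
                gate = friedman_p is None or friedman_p < alpha
                row[f"p_{c.name}"] = pval
                row[f"p_adj_{c.name}"] = ap
                row[f"significant_{c.name}"] = bool(rj and gate)
                row[f"test_{c.name}"] = label
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
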