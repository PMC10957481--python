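"""Differential clone-abundance calling between two visits of one patient.

For every clonotype in the union of a visit pair, a two-sided Fisher exact
test compares the 2×2 table ``[[count_a, total_a − count_a], [count_b,
total_b − count_b]]`` against the null that the clone's population abundance
is identical in the two samples.  P values are Benjamini–Hochberg adjusted
(m = number of clones tested in the pair) and clones with ``q < alpha``
(default 0.01) are called expanded or contracted by the direction of the
frequency change.  Significant expanded clones absent at the earlier visit
and detected above a read threshold (default: strictly more than 5
templates) are additionally labeled newly detected.

The two-sided p-value is the sum of hypergeometric outcome probabilities not
exceeding the observed one, with the conventional ``1 + 1e-7`` relative tie
tolerance (the same rule as R's fisher.test and scipy) so that mathematically
tied tables are counted despite floating-point noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .repertoire_io import RepertoireSample
from .repertoire_stats import clonality, morisita_horn

#: significance threshold on BH-adjusted p-values
DEFAULT_ALPHA = 0.01
#: newly-detected rule: count at the later visit must exceed this many reads
DEFAULT_READ_THRESHOLD = 5

EXPANDED = "expanded"
CONTRACTED = "contracted"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class CloneTestRecord:
    rearrangement_id: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    p_value: float
    q_value: float
    direction: str
    newly_detected: bool


@dataclass(frozen=True)
class DynamicsSummary:
    patient_id: str
    visit_pair: tuple[str, str]
    n_tested: int
    n_expanded: int
    n_contracted: int
    n_newly_detected_expanded: int
    clonality_a: float
    clonality_b: float
    morisita_horn: float


def _two_sided_fisher(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    s = count_a + count_b
    if s == 0 or s == total_a + total_b:
        return 1.0
    kmin = max(0, s - total_b)
    kmax = min(s, total_a)
    k = np.arange(kmin, kmax + 1)
    # log hypergeometric weights over the support, up to a common constant
    logw = (
        -gammaln(k + 1)
        - gammaln(total_a - k + 1)
        - gammaln(s - k + 1)
        - gammaln(total_b - s + k + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[count_a - kmin]
    p = w[w <= w_obs * (1.0 + 1e-7)].sum() / w.sum()
    # extreme tables underflow in double precision; keep p strictly positive
    return float(min(1.0, max(p, 1e-300)))


def fisher_clone_test(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p-value for one clone across two samples."""
    for cnt, tot in ((count_a, total_a), (count_b, total_b)):
        if tot <= 0:
            raise ValidationError(f"sample total must be positive, got {tot}")
        if cnt < 0 or cnt > tot:
            raise ValidationError(f"count {cnt} outside [0, {tot}]")
    return _two_sided_fisher(count_a, total_a, count_b, total_b)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_dynamics(
    a: RepertoireSample,
    b: RepertoireSample,
    alpha: float = DEFAULT_ALPHA,
    read_threshold: int = DEFAULT_READ_THRESHOLD,
    *,
    require_significance: bool = True,
) -> tuple[list[CloneTestRecord], DynamicsSummary]:
    """Test every clonotype of a within-patient visit pair for abundance change.

    ``require_significance=False`` switches the newly-detected rule to the
    looser absence-plus-count reading (no Fisher significance required), for
    sensitivity analysis; in that mode newly-detected clones need not carry an
    ``expanded`` direction label.
    """
    if a.patient_id != b.patient_id:
        raise ValidationError(
            f"visit pair spans two patients: {a.patient_id} vs {b.patient_id}"
        )
    a.require_nonempty()
    b.require_nonempty()

    counts_a = a.counts()
    counts_b = b.counts()
    total_a = a.total_templates
    total_b = b.total_templates
    keys = sorted(set(counts_a) | set(counts_b))

    cache: dict[tuple[int, int], float] = {}
    p_values = np.empty(len(keys))
    ka = np.empty(len(keys), dtype=int)
    kb = np.empty(len(keys), dtype=int)
    for i, key in enumerate(keys):
        ca = counts_a.get(key, 0)
        cb = counts_b.get(key, 0)
        ka[i], kb[i] = ca, cb
        pv = cache.get((ca, cb))
        if pv is None:
            pv = _two_sided_fisher(ca, total_a, cb, total_b)
            cache[(ca, cb)] = pv
        p_values[i] = pv

    q_values = bh_adjust(p_values)
    freq_a = ka / total_a
    freq_b = kb / total_b
    significant = q_values < alpha

    records: list[CloneTestRecord] = []
    for i, key in enumerate(keys):
        if significant[i] and freq_b[i] > freq_a[i]:
            direction = EXPANDED
        elif significant[i] and freq_b[i] < freq_a[i]:
            direction = CONTRACTED
        else:
            direction = UNCHANGED
        meets_novel = ka[i] == 0 and kb[i] > read_threshold
        if require_significance:
            newly = direction == EXPANDED and meets_novel
        else:
            newly = meets_novel
        records.append(
            CloneTestRecord(
                rearrangement_id=key,
                count_a=int(ka[i]),
                count_b=int(kb[i]),
                total_a=total_a,
                total_b=total_b,
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                direction=direction,
                newly_detected=newly,
            )
        )

    n_expanded = sum(r.direction == EXPANDED for r in records)
    n_newly = sum(r.newly_detected for r in records)
    summary = DynamicsSummary(
        patient_id=a.patient_id,
        visit_pair=(a.visit, b.visit),
        n_tested=len(records),
        n_expanded=n_expanded,
        n_contracted=sum(r.direction == CONTRACTED for r in records),
        n_newly_detected_expanded=n_newly,
        clonality_a=clonality(a).clonality,
        clonality_b=clonality(b).clonality,
        morisita_horn=morisita_horn(a, b).morisita_horn,
    )
    if require_significance:
        assert summary.n_newly_detected_expanded <= summary.n_expanded <= summary.n_tested
    return records, summary


def paired_signed_rank(deltas: Sequence[float], exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p; exact null for small n.

    Zero differences are dropped before ranking.  Uses the exact permutation
    null distribution for n ≤ ``exact_max_n`` nonzero pairs, and the normal
    approximation with continuity correction above.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    if d.size < 2:
        raise ValidationError("fewer than 2 nonzero paired differences")
    method = "exact" if d.size <= exact_max_n else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def cohort_visit_comparison(
    values: pd.DataFrame | Mapping[str, Mapping[str, float]],
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Paired signed-rank tests of a per-patient statistic between visits.

    ``values`` is patients × visits (rows = patients).  Each comparison uses
    only patients with both visits present; comparisons with fewer than two
    nonzero paired differences are skipped with a warning.  P values are
    BH-adjusted across the comparison set.  Per-patient deltas are returned
    for waterfall-style output.
    """
    df = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    rows = []
    for va, vb in comparisons:
        if va not in df.columns or vb not in df.columns:
            warnings.warn(f"comparison {va} vs {vb}: visit missing, skipped",
                          stacklevel=2)
            continue
        paired = df[[va, vb]].dropna()
        deltas = (paired[vb] - paired[va]).to_numpy()
        n_nonzero = int(np.count_nonzero(deltas))
        if len(paired) < 2 or n_nonzero < 2:
            warnings.warn(
                f"comparison {va} vs {vb}: fewer than 2 informative pairs, skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "visit_a": va,
                "visit_b": vb,
                "n_pairs": len(paired),
                "p_value": paired_signed_rank(deltas),
                "median_delta": float(np.median(deltas)),
                "deltas": dict(zip(paired.index, deltas)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["visit_a", "visit_b", "n_pairs", "p_value",
                       "median_delta", "deltas"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
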