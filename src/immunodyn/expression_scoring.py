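"""Gene-signature scoring and subgroup comparison for expression matrices.

Single-sample GSEA (ssGSEA) follows the Barbie-style construction: within a
sample, genes are ranked by expression (average rank for ties), in-set genes
are weighted by rank**alpha (alpha = 0.25 by default), and the enrichment
score is the sum over the descending-rank gene list of the difference between
the weighted in-set ECDF and the uniform out-of-set ECDF.  Scores are
optionally normalized by the range of ES across samples, emulating the usual
ssGSEA default.  The score is invariant to any strictly increasing
per-sample transform of expression because only ranks enter.

Panel (NanoString-style) counts are preprocessed by per-sample background
subtraction (mean of negative controls, plus an optional k·SD margin, floored
at zero) followed by housekeeping normalization: each sample is scaled by the
ratio of the cohort geometric-mean housekeeping sum to its own housekeeping
sum, so housekeeping totals agree across retained samples by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError

TPM = "tpm"
RAW_COUNTS = "raw_counts"
NORMALIZED_COUNTS = "normalized_counts"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a declared value kind."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    value_kind: str = TPM

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty gene set."""

    name: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValidationError(f"signature {self.name!r} is empty")
        norm = [g.strip().upper() for g in self.gene_symbols]
        if len(set(norm)) != len(norm):
            raise ValidationError(f"signature {self.name!r} has duplicate symbols")


@dataclass
class SignatureScores:
    signature: str
    scores: pd.Series  # index = sample ids
    fraction_genes_found: float
    genes_used: tuple[str, ...] = field(default_factory=tuple)


def load_signatures(path: str | Path | None = None) -> dict[str, GeneSignature]:
    """Load gene signatures from a YAML file (``name: [symbols]`` mapping).

    Without a path, the bundled signature file is used.  It carries the
    published 18-gene tumor inflammation signature (TIS) summarizing an
    IFN-γ-responsive, antigen-presenting, T-cell-inflamed microenvironment.
    """
    if path is None:
        text = (resources.files("immunodyn.data") / "signatures.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {
        name: GeneSignature(name=name, gene_symbols=tuple(symbols))
        for name, symbols in raw.items()
    }


def read_expression_table(path: str | Path, value_kind: str = TPM) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV (first column = gene symbol)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(values=df, value_kind=value_kind)


def _match_signature_genes(
    matrix: ExpressionMatrix, signature: GeneSignature, min_fraction: float
) -> list[str]:
    # case-insensitive exact match after whitespace stripping; no alias maps
    lookup = {str(g).strip().upper(): g for g in matrix.gene_ids}
    found, missing = [], []
    for sym in signature.gene_symbols:
        hit = lookup.get(sym.strip().upper())
        (found if hit is not None else missing).append(hit or sym)
    frac = len(found) / len(signature.gene_symbols)
    if frac < min_fraction:
        raise ValidationError(
            f"only {len(found)}/{len(signature.gene_symbols)} genes of "
            f"{signature.name!r} present; missing: {', '.join(missing)}"
        )
    return found


def ssgsea_scores(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    alpha: float = 0.25,
    normalize: bool = True,
    min_fraction: float = 0.5,
) -> SignatureScores:
    """Per-sample ssGSEA enrichment scores for one gene signature."""
    if matrix.value_kind not in (TPM, NORMALIZED_COUNTS):
        raise ValidationError(
            f"ssGSEA requires tpm or normalized_counts input, got {matrix.value_kind}"
        )
    n_genes = len(matrix.gene_ids)
    if n_genes < 2:
        raise ValidationError("ssGSEA needs at least 2 genes")
    genes_used = _match_signature_genes(matrix, signature, min_fraction)
    in_set = matrix.gene_ids.isin(genes_used).astype(bool)
    n_out = n_genes - in_set.sum()
    if n_out == 0:
        raise ValidationError("signature covers the whole matrix; no background genes")

    values = matrix.values.to_numpy(dtype=float)
    scores = {}
    for j, sample in enumerate(matrix.sample_ids):
        x = values[:, j]
        if np.ptp(x) == 0:
            warnings.warn(f"sample {sample}: constant expression", stacklevel=2)
        ranks = stats.rankdata(x)  # average rank for ties; high expression = high rank
        order = np.argsort(-ranks, kind="stable")  # descending
        in_ord = in_set[order]
        w = np.abs(ranks[order]) ** alpha
        w_in = np.where(in_ord, w, 0.0)
        ecdf_in = np.cumsum(w_in) / w_in.sum()
        ecdf_out = np.cumsum(~in_ord) / n_out
        scores[sample] = float(np.sum(ecdf_in - ecdf_out))

    series = pd.Series(scores, name=signature.name)
    if normalize:
        rng = series.max() - series.min()
        if rng > 0:
            series = series / rng
        else:
            warnings.warn("zero ES range across samples; normalization skipped",
                          stacklevel=2)
    return SignatureScores(
        signature=signature.name,
        scores=series,
        fraction_genes_found=len(genes_used) / len(signature.gene_symbols),
        genes_used=tuple(genes_used),
    )


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-scores (population SD); zero-variance rows become zeros."""
    if len(matrix.sample_ids) < 2:
        raise ValidationError("gene-wise z-scoring needs at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene row(s) set to zero",
                      stacklevel=2)
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=matrix.gene_ids, columns=matrix.sample_ids)
    # z-scores are signed; bypass the non-negativity check of __init__
    obj = ExpressionMatrix.__new__(ExpressionMatrix)
    obj.values = out
    obj.value_kind = "zscore"
    return obj


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    median_group_a: float
    median_group_b: float
    n_a: int
    n_b: int


def compare_groups(
    scores: SignatureScores | pd.Series,
    labels: pd.Series | dict,
    exact_max_n: int = 20,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Exact null for groups of at most ``exact_max_n`` each, otherwise the
    normal approximation with tie correction.  Deliberately uncorrected for
    multiplicity: subgroup contrasts are exploratory and reported as such.
    """
    values = scores.scores if isinstance(scores, SignatureScores) else scores
    lab = pd.Series(labels)
    common = values.index.intersection(lab.index)
    values, lab = values.loc[common], lab.loc[common]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    x = values[lab == groups[0]].to_numpy()
    y = values[lab == groups[1]].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    method = "exact" if max(x.size, y.size) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        p_value=float(res.pvalue),
        median_group_a=float(np.median(x)),
        median_group_b=float(np.median(y)),
        n_a=int(x.size),
        n_b=int(y.size),
    )


def normalize_panel_counts(
    raw: ExpressionMatrix,
    negative_controls: Sequence[str],
    housekeeping: Sequence[str],
    k_sd: float = 0.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Background-subtract and housekeeping-normalize raw panel counts.

    Returns the normalized matrix plus the list of excluded samples (those
    with a zero housekeeping sum after subtraction).
    """
    if raw.value_kind != RAW_COUNTS:
        raise ValidationError(f"expected raw_counts input, got {raw.value_kind}")
    for name, genes in (("negative control", negative_controls),
                        ("housekeeping", housekeeping)):
        missing = [g for g in genes if g not in raw.gene_ids]
        if missing:
            raise ValidationError(f"{name} genes absent from matrix: {missing}")

    df = raw.values.astype(float)
    neg = df.loc[list(negative_controls)]
    background = neg.mean(axis=0)
    if k_sd and len(negative_controls) > 1:
        background = background + k_sd * neg.std(axis=0, ddof=1)
    sub = (df - background).clip(lower=0.0)

    hk_sums = sub.loc[list(housekeeping)].sum(axis=0)
    excluded = list(hk_sums.index[hk_sums == 0])
    if excluded:
        warnings.warn(
            f"samples excluded (zero housekeeping signal): {excluded}", stacklevel=2
        )
    kept = hk_sums.index[hk_sums > 0]
    geo_mean = float(np.exp(np.log(hk_sums[kept]).mean()))
    normed = sub[kept] * (geo_mean / hk_sums[kept])
    return ExpressionMatrix(values=normed, value_kind=NORMALIZED_COUNTS), excluded


@dataclass
class LongitudinalModelResult:
    method: str  # "lmm" or "signed_rank"
    baseline: str
    effects: pd.DataFrame  # index = visit, columns = estimate, se, p_value
    lrt_p_value: float | None
    converged: bool


def longitudinal_signature_model(
    scores: pd.DataFrame,
    baseline: str = "C0D1",
) -> LongitudinalModelResult:
    """Mixed-model comparison of a signature score across visits.

    ``scores`` is long-format with columns ``patient_id``, ``visit``,
    ``score``.  Fits score ~ visit (fixed, baseline reference) with a
    patient-level random intercept; the overall visit effect is tested with a
    likelihood-ratio test (ML fits) against the no-visit-effect null, and
    per-visit contrasts vs baseline are reported with Wald p-values.  On
    non-convergence, falls back to per-visit paired signed-rank tests.
    """
    import statsmodels.formula.api as smf

    from .clone_dynamics import paired_signed_rank

    required = {"patient_id", "visit", "score"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"scores must have columns {sorted(required)}")
    visits = list(pd.unique(scores["visit"]))
    if baseline not in visits:
        raise ValidationError(f"baseline visit {baseline!r} not present")
    if len(visits) < 2:
        raise ValidationError("need at least 2 visits")
    n_repeat = (scores.groupby("patient_id")["visit"].nunique() >= 2).sum()
    if n_repeat < 3:
        raise ValidationError("need at least 3 patients with repeat measures")

    df = scores.copy()
    df["visit"] = pd.Categorical(
        df["visit"], categories=[baseline] + [v for v in visits if v != baseline]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("score ~ C(visit)", df, groups=df["patient_id"]).fit(
                reml=False
            )
            null = smf.mixedlm("score ~ 1", df, groups=df["patient_id"]).fit(
                reml=False
            )
        converged = bool(full.converged and null.converged)
    except Exception:
        converged = False

    if converged:
        lrt = 2.0 * (full.llf - null.llf)
        df_diff = len(visits) - 1
        lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df_diff))
        rows = []
        for v in visits:
            if v == baseline:
                continue
            term = f"C(visit)[T.{v}]"
            rows.append(
                {
                    "visit": v,
                    "estimate": float(full.params[term]),
                    "se": float(full.bse[term]),
                    "p_value": float(full.pvalues[term]),
                }
            )
        effects = pd.DataFrame(rows).set_index("visit")
        return LongitudinalModelResult(
            method="lmm", baseline=baseline, effects=effects,
            lrt_p_value=lrt_p, converged=True,
        )

    warnings.warn(
        "mixed model did not converge; falling back to paired signed-rank tests",
        stacklevel=2,
    )
    wide = scores.pivot_table(index="patient_id", columns="visit", values="score")
    rows = []
    for v in visits:
        if v == baseline:
            continue
        paired = wide[[baseline, v]].dropna()
        deltas = (paired[v] - paired[baseline]).to_numpy()
        est = float(np.median(deltas)) if deltas.size else float("nan")
        try:
            p = paired_signed_rank(deltas)
        except ValidationError:
            p = float("nan")
        rows.append({"visit": v, "estimate": est, "se": float("nan"), "p_value": p})
    effects = pd.DataFrame(rows).set_index("visit")
    return LongitudinalModelResult(
        method="signed_rank", baseline=baseline, effects=effects,
        lrt_p_value=None, converged=False,
    )
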