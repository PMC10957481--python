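"""Repertoire summary statistics: diversity, clonality and overlap.

Clonality is computed as ``1 − Pielou evenness``: with clone frequencies
``f_i`` over ``R`` productive clonotypes, Shannon entropy ``H = −Σ f_i ln f_i``
(natural log), evenness ``J = H / ln R``, and clonality ``C = 1 − J``.  The
logarithm base cancels in ``J`` so any base gives the same clonality; natural
logs are used throughout.  A monoclonal repertoire (``R = 1``) makes ``J``
0/0; it is defined as fully clonal (``C = 1``), the limit of concentration.

Repertoire overlap uses the Morisita–Horn index on template frequencies,
``MH = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)`` over the union of clonotype keys —
abundance-weighted, dominated by the largest clones, 1 for identical and 0
for disjoint repertoires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .repertoire_io import RepertoireSample


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    shannon_entropy: float
    pielou_evenness: float
    clonality: float


@dataclass(frozen=True)
class OverlapResult:
    morisita_horn: float
    shared_clonotypes: int


def frequency_vector(sample: RepertoireSample) -> dict[str, float]:
    """Clone frequencies ``template_count / total_templates`` (sum to 1)."""
    sample.require_nonempty()
    total = sample.total_templates
    return {
        k: c.template_count / total
        for k, c in sample.clonotypes.items()
        if c.template_count > 0
    }


def clonality(sample: RepertoireSample) -> DiversityResult:
    """Richness, Shannon entropy, Pielou evenness, and 1−evenness clonality."""
    freqs = np.array(list(frequency_vector(sample).values()))
    r = freqs.size
    h = float(-(freqs * np.log(freqs)).sum())
    if r == 1:
        warnings.warn(
            "monoclonal repertoire: evenness undefined, clonality set to 1",
            stacklevel=2,
        )
        return DiversityResult(richness=1, shannon_entropy=0.0,
                               pielou_evenness=0.0, clonality=1.0)
    j = h / np.log(r)
    c = float(min(1.0, max(0.0, 1.0 - j)))
    return DiversityResult(richness=int(r), shannon_entropy=h,
                           pielou_evenness=float(j), clonality=c)


def morisita_horn(a: RepertoireSample, b: RepertoireSample) -> OverlapResult:
    """Morisita–Horn similarity between two repertoires (template frequencies)."""
    fa = frequency_vector(a)
    fb = frequency_vector(b)
    keys = sorted(set(fa) | set(fb))  # stable order keeps sums reproducible
    p = np.array([fa.get(k, 0.0) for k in keys])
    q = np.array([fb.get(k, 0.0) for k in keys])
    mh = 2.0 * float(p @ q) / (float(p @ p) + float(q @ q))
    shared = int(np.sum((p > 0) & (q > 0)))
    return OverlapResult(morisita_horn=float(min(1.0, max(0.0, mh))),
                         shared_clonotypes=shared)
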