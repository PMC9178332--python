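"""Treatment-to-treatment inductive similarity.

Two views of how alike two stimuli are in the responses they provoke, both
built from contrasts of each treatment against the shared undamaged control:

* per-GO cosine similarity of signed trichotomous DEG vectors (+1 up, -1
  down, 0 non-significant over the term's genes), undefined when a term has
  no DEG under one of the treatments; and
* a global ordinary-least-squares regression of one treatment's per-gene
  log2 fold changes on the other's (slope 1, intercept 0 would mean
  identical responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ContrastResult


@dataclass
class DegVector:
    term_id: str
    genes: list[str]          # fixed gene order (term ∩ tested universe, sorted)
    values: np.ndarray        # entries in {-1, 0, +1}


@dataclass
class GoSimilarity:
    term_id: str
    similarity: float | None  # None = undefined (a zero vector)
    n_deg_a: int
    n_deg_b: int


@dataclass
class GlobalFcFit:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n_genes: int


def deg_vector(term_id: str, term_genes: set[str], contrast: ContrastResult) -> DegVector:
    """Signed call vector of a term's genes under one contrast.

    Gene order is the sorted intersection-with-universe order plus the term's
    untested genes (as zeros), so two contrasts over the same universe yield
    aligned vectors.
    """
    genes = sorted(term_genes)
    if not genes:
        raise ValueError(f"term {term_id!r} has no genes")
    calls = contrast.calls
    values = np.array([int(calls.get(g, 0)) for g in genes], dtype=int)
    return DegVector(term_id=term_id, genes=genes, values=values)


def cosine_similarity(x: DegVector, y: DegVector) -> GoSimilarity:
    """Dot-product cosine of two signed DEG vectors; undefined on zero norm."""
    if x.genes != y.genes:
        raise ValueError("DEG vectors must share the same gene order")
    nx_, ny_ = np.linalg.norm(x.values), np.linalg.norm(y.values)
    n_deg_a = int(np.count_nonzero(x.values))
    n_deg_b = int(np.count_nonzero(y.values))
    if nx_ == 0 or ny_ == 0:
        return GoSimilarity(x.term_id, None, n_deg_a, n_deg_b)
    sim = float(x.values @ y.values / (nx_ * ny_))
    return GoSimilarity(x.term_id, sim, n_deg_a, n_deg_b)


def go_similarity_table(
    annotation: dict[str, set[str]],
    contrast_a: ContrastResult,
    contrast_b: ContrastResult,
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Cosine similarity for every requested term (default: all annotated)."""
    if terms is None:
        terms = sorted(annotation)
    rows = []
    for term in terms:
        va = deg_vector(term, annotation[term], contrast_a)
        vb = deg_vector(term, annotation[term], contrast_b)
        s = cosine_similarity(va, vb)
        rows.append(
            {
                "term_id": term,
                "nA_deg": s.n_deg_a,
                "nB_deg": s.n_deg_b,
                "similarity": s.similarity if s.similarity is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["term_id", "nA_deg", "nB_deg", "similarity"])


def global_fc_regression(contrast_a: ContrastResult, contrast_b: ContrastResult) -> GlobalFcFit:
    """OLS of contrast A's log2FC on contrast B's over their shared genes."""
    shared = contrast_a.table.index.intersection(contrast_b.table.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for the regression")
    y = contrast_a.table.loc[shared, "log2fc"].to_numpy()
    x = contrast_b.table.loc[shared, "log2fc"].to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regressor: log2FC constant in contrast B")
    fit = stats.linregress(x, y)
    return GlobalFcFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_genes=len(shared),
    )
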