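"""Classification of genes into 27 expression patterns and module extraction.

Three cumulative contrasts (control->W_W, W_W->W_ABOS, W_ABOS->W_OS) each
give a trichotomous call per gene; the ordered triple of calls is the gene's
pattern code, one of 3^3 = 27.  Pattern 1 is the null code (0,0,0): no
significant change at any component addition.  Every non-null code whose
gene count reaches the minimum size (default 300) forms a gene module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .diffexpr import ContrastResult

MIN_MODULE_SIZE = 300

Code = tuple[int, int, int]


def all_codes(k: int = 3) -> list[tuple[int, ...]]:
    """All 3^k trichotomous codes in base-3 rank order (-1 < 0 < +1)."""
    return list(product((-1, 0, 1), repeat=k))


def pattern_index_table(k: int = 3) -> dict[tuple[int, ...], int]:
    """Code -> 1-based pattern index; the null code is index 1, the rest
    follow in base-3 rank order."""
    null = tuple([0] * k)
    codes = [null] + [c for c in all_codes(k) if c != null]
    return {c: i + 1 for i, c in enumerate(codes)}


@dataclass
class PatternAssignment:
    """Per-gene pattern codes over the cumulative contrasts.

    ``codes`` maps gene id -> code triple; ``untested`` lists genes missing
    from at least one contrast (no trichotomous call possible there).
    """

    codes: dict[str, Code]
    untested: list[str]
    index_table: dict[Code, int]

    def pattern_of(self, gene: str) -> int:
        return self.index_table[self.codes[gene]]

    def counts(self) -> pd.Series:
        """Gene count per code, over all 27 codes (zeros included)."""
        tally = {c: 0 for c in self.index_table}
        for code in self.codes.values():
            tally[code] += 1
        idx = sorted(tally, key=self.index_table.get)
        return pd.Series(
            [tally[c] for c in idx],
            index=pd.MultiIndex.from_tuples(idx, names=["d1", "d2", "d3"]),
            name="n_genes",
        )


@dataclass
class GeneModule:
    module_id: str
    code: Code
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


def classify_patterns(r1: ContrastResult, r2: ContrastResult, r3: ContrastResult) -> PatternAssignment:
    """Combine three contrasts' calls into per-gene pattern codes.

    Genes absent from any contrast (dropped by its mean-count filter) go to
    the untested stratum and receive no code.
    """
    universes = [set(r.table.index) for r in (r1, r2, r3)]
    tested = universes[0] & universes[1] & universes[2]
    if not tested:
        raise ValueError("no gene is tested in all three contrasts")
    everything = universes[0] | universes[1] | universes[2]
    untested = sorted(everything - tested)

    calls = [r.calls for r in (r1, r2, r3)]
    codes = {
        g: (int(calls[0][g]), int(calls[1][g]), int(calls[2][g]))
        for g in sorted(tested)
    }
    return PatternAssignment(codes=codes, untested=untested, index_table=pattern_index_table())


def extract_modules(pa: PatternAssignment, min_size: int = MIN_MODULE_SIZE) -> list[GeneModule]:
    """One module per non-null code with >= min_size genes, largest first.

    Ties in size break by pattern index so the ordering is deterministic and
    independent of gene ordering.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_code: dict[Code, set[str]] = {}
    for g, code in pa.codes.items():
        if code != (0, 0, 0):
            by_code.setdefault(code, set()).add(g)
    eligible = [(code, genes) for code, genes in by_code.items() if len(genes) >= min_size]
    eligible.sort(key=lambda cg: (-len(cg[1]), pa.index_table[cg[0]]))
    return [
        GeneModule(module_id=f"module_{i+1}", code=code, genes=frozenset(genes))
        for i, (code, genes) in enumerate(eligible)
    ]


def summarize_counts(total: int, pattern1: int, module_sizes: list[int]) -> dict:
    """Summary arithmetic from raw counts (2-decimal rounding).

    ``responsive`` = total - pattern-1 genes; ``module_coverage_pct`` =
    sum(module sizes) / responsive * 100, or None when nothing responded.
    """
    responsive = total - pattern1
    summary = {
        "total_genes": total,
        "pattern1_genes": pattern1,
        "pattern1_pct": round(100.0 * pattern1 / total, 2) if total else None,
        "responsive_genes": responsive,
        "module_sizes": list(module_sizes),
        "modules_total": int(sum(module_sizes)),
        "module_coverage_pct": (
            round(100.0 * sum(module_sizes) / responsive, 2) if responsive > 0 else None
        ),
    }
    return summary


def pattern_summary(pa: PatternAssignment, modules: list[GeneModule]) -> dict:
    """Headline numbers of a pattern assignment plus its modules."""
    if not pa.codes:
        raise ValueError("empty pattern assignment")
    total = len(pa.codes)
    pattern1 = sum(1 for c in pa.codes.values() if c == (0, 0, 0))
    out = summarize_counts(total, pattern1, [m.size for m in modules])
    out["untested_genes"] = len(pa.untested)
    out["module_codes"] = [m.code for m in modules]
    return out
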