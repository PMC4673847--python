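"""Gene-set over/under-representation testing.

A generic two-sided Fisher exact (hypergeometric) test of a study gene set
against a background gene->term annotation map, with Bonferroni correction
over the number of terms tested.  The background universe is the full set
of genes in the supplied map; study genes absent from the map are dropped
and logged.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    n_study_with_term: int
    n_study: int
    n_background_with_term: int
    n_background: int
    direction: str  # over | under
    p_raw: float
    p_bonferroni: float

    @property
    def expected(self) -> float:
        return self.n_study * self.n_background_with_term / self.n_background


def read_gene_term_map(path: str | Path) -> dict[str, set[str]]:
    """TSV (gene_id, term_id; header required) -> term -> set of genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene_id", "term_id"]:
        raise ValueError(f"{path}: expected header gene_id<TAB>term_id")
    terms: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        terms.setdefault(term, set()).add(gene)
    return terms


def test_terms(
    study_genes: Iterable[str],
    gene_term_map: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact test of every term against the study set.

    The 2x2 table per term is (study vs rest) x (annotated vs not);
    direction is the sign of observed minus expected; terms with zero
    annotated genes are excluded; Bonferroni multiplies by the number of
    terms actually tested, capped at 1.
    """
    background = set().union(*gene_term_map.values()) if gene_term_map else set()
    study_all = set(study_genes)
    if not study_all:
        raise ValueError("empty study gene set")
    study = study_all & background
    dropped = study_all - background
    if dropped:
        log.info(
            "test_terms: %d of %d study genes absent from the reference list",
            len(dropped), len(study_all),
        )
    if not study:
        raise ValueError("no study gene is present in the annotation map")
    n_bg = len(background)
    n_study = len(study)
    testable = {t: g for t, g in gene_term_map.items() if g}
    n_tests = len(testable)
    results = []
    for term in sorted(testable):
        annotated = testable[term]
        k = len(study & annotated)
        big_k = len(annotated)
        table = [
            [k, n_study - k],
            [big_k - k, (n_bg - n_study) - (big_k - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        expected = n_study * big_k / n_bg
        results.append(
            EnrichmentResult(
                term_id=term,
                n_study_with_term=k,
                n_study=n_study,
                n_background_with_term=big_k,
                n_background=n_bg,
                direction="over" if k >= expected else "under",
                p_raw=float(p),
                p_bonferroni=min(1.0, float(p) * n_tests),
            )
        )
    return results


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "n_study_with_term": r.n_study_with_term,
                "n_study": r.n_study,
                "n_background_with_term": r.n_background_with_term,
                "n_background": r.n_background,
                "expected": r.expected,
                "direction": r.direction,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ]
    )
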