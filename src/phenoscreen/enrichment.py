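"""Hypergeometric over-representation of annotation terms in a hit list.

Given X hit genes out of a background of N, a term annotating n background
genes and x of the hits, the one-sided upper-tail hypergeometric probability
P(K >= x) measures over-representation.  Both Bonferroni (m = number of
terms tested) and Benjamini-Hochberg corrections are reported.  The same
machinery tests a single gene set (e.g. the environmental stress response
genes) against the hit list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    term_name: str
    x: int  # hits annotated to the term
    X: int  # total hits
    n: int  # background genes annotated
    N: int  # background size
    p_raw: float
    p_bonferroni: float
    q_bh: float


def hypergeom_pvalue(x: int, X: int, n: int, N: int) -> float:
    """Upper-tail P(K >= x) for K = |hits ∩ term|, drawing X genes from a
    background of N containing n term members.

    scipy evaluates the tail in log space, so small p-values at genome
    scale are numerically stable.
    """
    if not (0 <= x <= min(X, n) and x <= X <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts x={x}, X={X}, n={n}, N={N}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, n, X))


def read_annotation(path) -> pd.DataFrame:
    """gene->term table (TSV: gene_id, term_id[, term_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df[["gene_id", "term_id", "term_name"]]


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        ]


def enrich_terms(
    hit_genes: Iterable[str],
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list[TermEnrichment]:
    """One enrichment record per term with at least one annotated hit.

    Hits must be a subset of the background (offenders are listed in the
    error).  Output is sorted by raw p-value, ties broken by term id; both
    corrections use m = number of terms actually tested.
    """
    hits = set(hit_genes)
    bg = set(background)
    strays = sorted(hits - bg)
    if strays:
        raise ValueError(f"hit genes absent from background: {strays}")
    if isinstance(annotation, pd.DataFrame):
        term_names = dict(zip(annotation["term_id"], annotation["term_name"]))
        term_genes: dict[str, set[str]] = {}
        for gene, term in zip(annotation["gene_id"], annotation["term_id"]):
            term_genes.setdefault(term, set()).add(gene)
    else:
        term_genes = {t: set(g) for t, g in annotation.items()}
        term_names = {t: t for t in term_genes}

    X, N = len(hits), len(bg)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term] & bg
        x = len(members & hits)
        if x == 0:
            continue
        n = len(members)
        rows.append((term, x, n, hypergeom_pvalue(x, X, n, N)))
    if not rows:
        return []

    pvals = [r[3] for r in rows]
    p_bonf = multipletests(pvals, method="bonferroni")[1]
    q_bh = multipletests(pvals, method="fdr_bh")[1]
    results = [
        TermEnrichment(term, term_names.get(term, term), x, X, n, N,
                       p, float(pb), float(qb))
        for (term, x, n, p), pb, qb in zip(rows, p_bonf, q_bh)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def geneset_overlap_test(
    hit_genes: Iterable[str], gene_set: Iterable[str], background: Iterable[str]
) -> tuple[float, float]:
    """Fraction of hits inside the gene set and the one-sided p for that
    overlap under random sampling from the background."""
    hits = set(hit_genes)
    bg = set(background)
    gs = set(gene_set)
    strays = sorted((hits | gs) - bg)
    if strays:
        raise ValueError(f"genes absent from background: {strays}")
    if not hits:
        raise ValueError("empty hit list")
    x = len(hits & gs)
    fraction = x / len(hits)
    p = hypergeom_pvalue(x, len(hits), len(gs), len(bg))
    return fraction, p


def enrichment_table(results: Sequence[TermEnrichment]) -> pd.DataFrame:
    """Tabular view mirroring the screen's enrichment report: counts, the
    x/X and n/N percentages, raw and adjusted p-values."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "x": r.x,
                "X": r.X,
                "n": r.n,
                "N": r.N,
                "x_over_X_pct": 100.0 * r.x / r.X,
                "n_over_N_pct": 100.0 * r.n / r.N,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "q_bh": r.q_bh,
            }
            for r in results
        ]
    )
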