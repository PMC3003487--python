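"""GO-slim overrepresentation of a gene set against an annotated background.

The statistic is the classical one-sided (upper-tail) hypergeometric test:
for a study set of size ``n`` drawn from a background of ``N`` genes of
which ``K`` carry a term, the p-value of observing ``k`` or more annotated
study genes is ``P(X >= k)``.  Raw p-values across all tested terms are
corrected by the Benjamini–Hochberg step-up FDR procedure, and a
BiNGO-style color scale maps adjusted p-values to a 0..1 significance
intensity (0 at the significance level, saturating at 1 five orders of
magnitude below it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Set

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, SignetError


@dataclass
class AnnotationMap:
    """Gene -> GO-term annotations plus optional term names/parents.

    ``term_parents`` (child -> set of parents) is carried for reporting
    only; annotations are *not* propagated up the hierarchy unless
    :meth:`propagated` is called explicitly (GO-slim annotation sets are
    already collapsed to high-level terms).
    """

    gene_to_terms: dict
    term_names: dict = field(default_factory=dict)
    term_parents: dict = field(default_factory=dict)

    @property
    def genes(self) -> Set[str]:
        return set(self.gene_to_terms)

    @property
    def terms(self) -> Set[str]:
        out: Set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= set(ts)
        return out

    def term_to_genes(self, background: Optional[Set[str]] = None) -> dict:
        bg = self.genes if background is None else set(background)
        out: dict = {}
        for gene, terms in self.gene_to_terms.items():
            if gene not in bg:
                continue
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out

    def restricted_to(self, background: Iterable[str]) -> "AnnotationMap":
        bg = set(background)
        return AnnotationMap(
            gene_to_terms={
                g: set(t) for g, t in self.gene_to_terms.items() if g in bg
            },
            term_names=dict(self.term_names),
            term_parents=dict(self.term_parents),
        )

    def propagated(self) -> "AnnotationMap":
        """Annotate every gene to all ancestors of its terms (off by default)."""
        def ancestors(term: str) -> Set[str]:
            seen: Set[str] = set()
            stack = [term]
            while stack:
                t = stack.pop()
                for parent in self.term_parents.get(t, ()):
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)
            return seen

        gene_to_terms = {}
        for gene, terms in self.gene_to_terms.items():
            full = set(terms)
            for t in terms:
                full |= ancestors(t)
            gene_to_terms[gene] = full
        return AnnotationMap(gene_to_terms, dict(self.term_names), dict(self.term_parents))

    @classmethod
    def from_tsv(cls, source) -> "AnnotationMap":
        """Two-column ``gene<TAB>term`` TSV ('#'/'!' lines are comments)."""
        from .io import _open_read

        handle, close = _open_read(source)
        try:
            gene_to_terms: dict = {}
            for raw in handle:
                line = raw.strip()
                if not line or line.startswith(("#", "!")):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    parts = line.split()
                if len(parts) < 2:
                    continue
                gene, term = parts[0].strip(), parts[1].strip()
                gene_to_terms.setdefault(gene, set()).add(term)
            return cls(gene_to_terms)
        finally:
            if close:
                handle.close()

    @classmethod
    def from_gaf(cls, source) -> "AnnotationMap":
        """GAF 2.x annotation file; NOT-qualified rows are skipped."""
        from .io import _open_read

        handle, close = _open_read(source)
        try:
            gene_to_terms: dict = {}
            for raw in handle:
                if raw.startswith("!") or not raw.strip():
                    continue
                cols = raw.rstrip("\n").split("\t")
                if len(cols) < 5:
                    continue
                symbol, qualifier, term = cols[2], cols[3], cols[4]
                if "NOT" in qualifier.split("|"):
                    continue
                if symbol and term:
                    gene_to_terms.setdefault(symbol, set()).add(term)
            return cls(gene_to_terms)
        finally:
            if close:
                handle.close()


def load_obo_term_names(source) -> dict:
    """Term id -> name from an OBO ontology file (names only)."""
    import obonet

    graph = obonet.read_obo(source)
    return {t: d.get("name", "") for t, d in graph.nodes(data=True)}


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` carry the term; ``n`` study genes
    of which ``k`` carry it.  Computed through log-space survival routines,
    exactly 1.0 at k = 0.
    """
    if not (0 <= k <= n <= N):
        raise ParameterError(f"require 0 <= k <= n <= N, got k={k} n={n} N={N}")
    if not (0 <= K <= N):
        raise ParameterError(f"require 0 <= K <= N, got K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> list:
    """Benjamini–Hochberg step-up adjusted p-values, aligned to input order.

    Adjusted values are clipped at 1 and clamped to be >= the raw value, so
    ``p_adj >= p_raw`` holds exactly in floating point.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return [float(x) for x in np.minimum(np.maximum(adjusted, p), 1.0)]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's contingency counts and raw/adjusted p-values."""

    term_id: str
    term_name: str
    k: int  # study genes carrying the term
    n: int  # study-set size
    K: int  # background genes carrying the term
    N: int  # background size
    p_raw: float
    p_adj: float
    significant: bool


def enrich_gene_set(
    study: Iterable[str],
    annot: AnnotationMap,
    background: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
) -> list:
    """Overrepresentation of ``study`` in every term it touches.

    The background defaults to all annotated genes of ``annot``.  Returns
    one :class:`EnrichmentRow` per term with at least one study-set gene,
    sorted by adjusted p-value then term id; rows with ``p_adj <= alpha``
    are flagged significant.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    study_set = set(study)
    bg = annot.genes if background is None else set(background)
    missing = sorted(study_set - bg)
    if missing:
        raise SignetError(
            "study genes absent from the background population: "
            + ", ".join(missing)
        )
    term_genes = annot.term_to_genes(bg)
    n, N = len(study_set), len(bg)
    tested = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & study_set)
        if k == 0:
            continue
        K = len(genes)
        tested.append((term, k, K, hypergeom_upper_tail(k, K, n, N)))
    if not tested:
        return []
    adjusted = bh_adjust([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            term_id=term,
            term_name=annot.term_names.get(term, ""),
            k=k,
            n=n,
            K=K,
            N=N,
            p_raw=p_raw,
            p_adj=p_adj,
            significant=p_adj <= alpha,
        )
        for (term, k, K, p_raw), p_adj in zip(tested, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.term_id))
    return rows


def significance_color(p_adj: float, alpha: float = 0.05) -> Optional[float]:
    """BiNGO-style color intensity for a significant adjusted p-value.

    0.0 at ``p_adj == alpha``, linear in ``-log10(p_adj / alpha)`` and
    saturating at 1.0 once ``p_adj`` is five or more orders of magnitude
    below ``alpha``.  Non-significant values (``p_adj > alpha``) return
    ``None`` as the distinguished "not significant" code.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if p_adj > alpha:
        return None
    return min(1.0, max(0.0, math.log10(alpha / p_adj) / 5.0))
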