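"""Hypergeometric over-representation analysis of target sets.

For a query set of ``n`` targets drawn from a background of ``N`` subjects,
and an annotation term covering ``K`` of them, the probability of observing
``k`` or more annotated targets in the query under uniform sampling without
replacement is the upper tail of the hypergeometric distribution:

.. math:: p = P[X \\ge k], \\quad X \\sim \\mathrm{Hypergeom}(N, K, n).

Terms with ``p < alpha`` (default 0.05, raw) are flagged significant.  An
optional EASE-style correction (the overlap reduced by one before taking the
tail, as popularized by the DAVID service) is available for sensitivity
analysis, and Benjamini-Hochberg q-values can be added on request; neither is
applied by default.  The background defaults to the subjects of the supplied
annotation universe, not a whole genome — enrichment is background-sensitive
and the choice is deliberately explicit.

Pathway-level results can be folded into five coarse function modules
(inflammatory, immune, metabolic, infection, other) for network overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EnrichmentError

__all__ = [
    "FUNCTION_MODULES",
    "TermUniverse",
    "EnrichmentResult",
    "EnrichmentAnalysis",
    "hypergeom_enrich",
    "group_by_function_module",
]

#: Default coarse pathway groupings used as the fifth network layer.
FUNCTION_MODULES = (
    "inflammatory regulation",
    "immune regulation",
    "metabolic regulation",
    "bacterial infection or mycosis",
    "other function",
)


@dataclass(frozen=True)
class TermUniverse:
    """An annotation universe: a background set and term -> subject subsets."""

    background: frozenset[str]
    terms: Mapping[str, frozenset[str]]
    term_kind: str = "pathway"

    def __post_init__(self) -> None:
        if not self.background:
            raise EnrichmentError("background must be non-empty")
        for term, subjects in self.terms.items():
            if not subjects <= self.background:
                raise EnrichmentError(
                    f"term {term!r} annotates subjects outside the background")

    @classmethod
    def from_annotation_table(cls, table: pd.DataFrame,
                              term_kind: str | None = None,
                              background: Iterable[str] | None = None
                              ) -> "TermUniverse":
        """Build a universe from a (subject_id, term_id, term_kind) frame.

        The background defaults to every subject appearing in the table.
        """
        df = table
        if term_kind is not None:
            df = df[df["term_kind"] == term_kind]
        kinds = df["term_kind"].unique().tolist() if len(df) else [term_kind or "pathway"]
        if len(kinds) > 1:
            raise EnrichmentError(
                f"annotation table mixes term kinds {kinds}; pass term_kind=")
        bg = frozenset(str(s) for s in (
            background if background is not None else df["subject_id"]))
        terms = {str(t): frozenset(str(s) for s in grp["subject_id"])
                 for t, grp in df.groupby("term_id")}
        return cls(background=bg, terms=terms, term_kind=str(kinds[0]))


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts and upper-tail hypergeometric P-value for one term."""

    term_id: str
    term_kind: str
    k: int            # overlap between query and term
    K: int            # term size in the background
    n: int            # query size (within background)
    N: int            # background size
    p_value: float
    significant: bool
    q_value: float | None = None


@dataclass(frozen=True)
class EnrichmentAnalysis:
    """Sorted enrichment results plus bookkeeping of dropped query ids."""

    results: tuple[EnrichmentResult, ...]
    n_dropped: int
    alpha: float

    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        cols = ["term_id", "term_kind", "k", "K", "n", "N",
                "p_value", "q_value", "significant"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols}
                             for r in self.results], columns=cols)


def hypergeom_enrich(query: Iterable[str], universe: TermUniverse,
                     alpha: float = 0.05, ease: bool = False,
                     fdr: bool = False) -> EnrichmentAnalysis:
    """Test every term of the universe for over-representation in the query.

    Query ids outside the background are dropped (their count is reported on
    the result).  Results are sorted by ascending P-value with ties broken by
    term id for stable output.  With ``ease=True`` the overlap is reduced by
    one before taking the tail (a conservative DAVID-style variant); with
    ``fdr=True`` Benjamini-Hochberg q-values are attached and significance is
    assessed on q instead of raw p.
    """
    qset = {str(q) for q in query}
    dropped = len(qset - universe.background)
    qset &= universe.background
    n, N = len(qset), len(universe.background)
    raw: list[tuple[str, int, int, float]] = []
    for term_id in sorted(universe.terms):
        members = universe.terms[term_id]
        K = len(members)
        k = len(qset & members)
        if n == 0:
            p = 1.0
        else:
            shift = 1 if ease else 0
            # P[X >= k - shift]; sf(x) = P[X > x]
            p = float(hypergeom.sf(k - 1 - shift, N, K, n))
        raw.append((term_id, k, K, min(p, 1.0)))
    if fdr and raw:
        _, qvals, _, _ = multipletests([r[3] for r in raw], method="fdr_bh")
    else:
        qvals = [None] * len(raw)
    results = [
        EnrichmentResult(
            term_id=t, term_kind=universe.term_kind, k=k, K=K, n=n, N=N,
            p_value=p, q_value=q,
            significant=(q < alpha) if q is not None else (p < alpha))
        for (t, k, K, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return EnrichmentAnalysis(results=tuple(results), n_dropped=dropped,
                              alpha=alpha)


def group_by_function_module(results: Sequence[EnrichmentResult],
                             module_map: pd.DataFrame) -> pd.DataFrame:
    """Summarize pathway results per function module.

    ``module_map`` is an annotation frame mapping ``subject_id`` (pathway
    term id) to ``term_id`` (module label); it must be a function — a pathway
    mapped to two modules is an error.  Pathways absent from the map land in
    the catch-all "other function" module.  Returns one row per module with
    the term count and number of significant terms; counts are additive over
    the input.
    """
    mapping: dict[str, str] = {}
    for row in module_map.itertuples(index=False):
        pathway, module = str(row.subject_id), str(row.term_id)
        if pathway in mapping and mapping[pathway] != module:
            raise EnrichmentError(
                f"pathway {pathway!r} mapped to two modules: "
                f"{mapping[pathway]!r} and {module!r}")
        mapping[pathway] = module
    modules = list(FUNCTION_MODULES)
    for m in mapping.values():
        if m not in modules:
            modules.append(m)
    counts = {m: 0 for m in modules}
    signif = {m: 0 for m in modules}
    for r in results:
        module = mapping.get(r.term_id, "other function")
        counts[module] += 1
        if r.significant:
            signif[module] += 1
    return pd.DataFrame({"module": modules,
                         "n_terms": [counts[m] for m in modules],
                         "n_significant": [signif[m] for m in modules]})
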