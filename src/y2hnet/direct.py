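"""Fisher-exact gene-set enrichment of the direct interactor set.

The seed proteins (direct bait interactors) are tested for overrepresentation
in each annotation term within the *tested universe* — the ORF space the
screen could have sampled — using the one-sided (upper-tail) Fisher exact
test.  Two multiple-testing dialects are provided:

``paper_simple``
    corrected_i = min(1, p_i * m / rank_i) with ranks assigned by ascending
    p.  This is the Benjamini-Hochberg per-rank scaling *without* the
    step-up cumulative-minimum pass, which is the dialect the published
    enrichment tables were computed with (its fingerprint: corrected values
    need not be monotone in rank).

``standard_bh``
    the textbook step-up procedure with cumulative minimum from the largest
    rank; monotone by construction.

The test count ``m`` may exceed the number of p-values handed in (terms
filtered out of the report still count toward the correction).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import GeneSetCollection, Universe

__all__ = [
    "ContingencyTable",
    "CorrectionConfig",
    "EnrichmentRow",
    "InfiniteOddsRatioError",
    "build_table",
    "fisher_one_sided",
    "infer_test_count",
    "multiple_test_correct",
    "odds_ratio",
    "run_direct_enrichment",
]


class InfiniteOddsRatioError(ZeroDivisionError):
    """b*c = 0 with the zero-cell correction disabled."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 seed-by-term table inside the universe.

    ``a``: seeds annotated to the term; ``b``: seeds not annotated;
    ``c``: non-seed universe genes annotated; ``d``: the remainder.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        """Universe size."""
        return self.a + self.b + self.c + self.d

    @property
    def n_annotated(self) -> int:
        """Term size within the universe."""
        return self.a + self.c

    @property
    def n_seeds(self) -> int:
        return self.a + self.b


@dataclass(frozen=True)
class CorrectionConfig:
    """Multiple-testing settings: dialect and the number of tests ``m``."""

    mode: str = "paper_simple"
    m: int | None = None  # None: use the number of tested terms

    def __post_init__(self) -> None:
        if self.mode not in ("paper_simple", "standard_bh"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be positive")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    obs: int
    odds_ratio: float
    p: float
    p_corrected: float
    rank: int

    # unified result-table fields (see io.write_enrichment_tsv)
    @property
    def p_or_fdr(self) -> float:
        return self.p

    @property
    def corrected(self) -> float:
        return self.p_corrected


def build_table(
    seeds: Iterable[str], term_members: Iterable[str], universe: Universe
) -> ContingencyTable:
    """Intersect seeds and term with the universe and build the 2x2 table."""
    seeds_u = frozenset(seeds) & universe.genes
    if not seeds_u:
        raise ValueError("no seed lies in the universe; nothing to test")
    term_u = frozenset(term_members) & universe.genes
    a = len(seeds_u & term_u)
    b = len(seeds_u) - a
    c = len(term_u) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail Fisher exact p-value: P(X >= a).

    X is hypergeometric with population N = a+b+c+d, K = a+c annotated
    genes, and n = a+b draws (the seed set).
    """
    return float(
        hypergeom.sf(
            table.a - 1, table.n, table.n_annotated, table.n_seeds
        )
    )


def odds_ratio(
    table: ContingencyTable, zero_cell_correction: bool = True
) -> float:
    """Sample odds ratio (a*d)/(b*c).

    With ``zero_cell_correction`` the Haldane-Anscombe rule adds 0.5 to all
    four cells whenever any cell is zero.  Without it, a zero in b or c
    raises :class:`InfiniteOddsRatioError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if zero_cell_correction and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        raise InfiniteOddsRatioError(
            "odds ratio undefined (b*c = 0); enable zero_cell_correction"
        )
    return (a * d) / (b * c)


def multiple_test_correct(
    pvals: Sequence[float], cfg: CorrectionConfig
) -> list[float]:
    """Correct a rank-ordered p-value list.

    ``pvals`` must already be in rank order (ascending p, ties broken by
    term identifier); rank i is its 1-based position.  ``cfg.m`` defaults to
    ``len(pvals)`` and may be larger (never smaller).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(np.diff(p) < 0):
        raise ValueError("pvals must be sorted ascending (rank order)")
    m = cfg.m if cfg.m is not None else p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values ({p.size})")
    ranks = np.arange(1, p.size + 1)
    scaled = np.minimum(1.0, p * m / ranks)
    if cfg.mode == "paper_simple":
        return scaled.tolist()
    # standard step-up: cumulative minimum from the largest rank down
    return np.minimum.accumulate(scaled[::-1])[::-1].tolist()


def infer_test_count(
    pvals: Sequence[float],
    corrected: Sequence[float],
    ranks: Sequence[int] | None = None,
) -> int:
    """Recover the test count ``m`` from printed (raw, corrected) pairs.

    Under the ``paper_simple`` dialect corrected = p * m / rank, so each
    uncapped pair votes m = corrected * rank / p; the median vote is
    rounded to the nearest integer.  Pairs with corrected >= 1 (capped) are
    ignored.
    """
    p = np.asarray(pvals, dtype=float)
    c = np.asarray(corrected, dtype=float)
    r = (
        np.arange(1, p.size + 1)
        if ranks is None
        else np.asarray(ranks, dtype=float)
    )
    keep = (c < 1.0) & (p > 0)
    if not keep.any():
        raise ValueError("no uncapped pair to infer m from")
    votes = c[keep] * r[keep] / p[keep]
    return int(round(float(np.median(votes))))


def run_direct_enrichment(
    seeds: Iterable[str],
    collection: GeneSetCollection,
    universe: Universe,
    min_obs: int = 2,
    cfg: CorrectionConfig | None = None,
) -> list[EnrichmentRow]:
    """Test every term of a collection against the seed set.

    A term is *tested* if at least one of its members lies in the universe;
    the number of tested terms is the default correction count ``m``.  The
    report keeps rows with ``obs >= min_obs`` (published convention: at
    least two annotated seeds), sorted by ascending p with ties broken by
    term id.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    cfg = cfg or CorrectionConfig()
    seeds = frozenset(seeds)
    tested: list[tuple[str, str, ContingencyTable, float]] = []
    for term_id, gs in collection.sets.items():
        if not (gs.members & universe.genes):
            continue
        table = build_table(seeds, gs.members, universe)
        tested.append((term_id, gs.name, table, fisher_one_sided(table)))
    if not tested:
        return []
    if cfg.m is None:
        cfg = CorrectionConfig(mode=cfg.mode, m=len(tested))
    tested.sort(key=lambda t: (t[3], t[0]))
    corrected = multiple_test_correct([t[3] for t in tested], cfg)
    rows = []
    for rank0, ((term_id, name, table, p), p_corr) in enumerate(
        zip(tested, corrected)
    ):
        if table.a < min_obs:
            continue
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                name=name,
                obs=table.a,
                odds_ratio=odds_ratio(table, zero_cell_correction=True),
                p=p,
                p_corrected=p_corr,
                rank=rank0 + 1,
            )
        )
    return rows
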