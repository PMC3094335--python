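"""EASE-style category overrepresentation and category-database upkeep.

Given a gene list drawn from a population (the platform base set) and a
database of named categories (bibliographic annotations or GO-derived
lists), each category is scored with the one-sided Fisher exact test
(upper hypergeometric tail) and its conservative EASE variant, which
removes one gene from the hit cell before computing the tail — a single
shared gene then carries no weight, which damps spurious hits from tiny
categories.  Benjamini–Hochberg q-values are reported across categories
as an advisory column.

Because bibliographic annotations age as gene names change, category
databases carry a release tag and can be refreshed to a newer release
through the lineage converter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import lineage as _lineage

logger = logging.getLogger(__name__)


class ReleaseMismatchError(ValueError):
    """Category database and gene list are on different releases; run
    refresh_categories first."""


@dataclass
class CategoryDatabase:
    """Named gene categories pinned to one annotation release."""

    categories: dict[str, tuple[str, frozenset[str]]]  # name -> (description, genes)
    release: str
    source: str = "bibliographic"

    def __post_init__(self):
        for name, (_, genes) in self.categories.items():
            if not genes:
                raise ValueError(f"category {name!r} has an empty gene set")

    @classmethod
    def from_gmt(cls, path, source: str = "bibliographic") -> "CategoryDatabase":
        """GMT-like TSV: a '#release <tag>' header line, then one category
        per line: name, description, tab-separated gene ids."""
        release = None
        cats: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#release"):
                    release = line.split(None, 1)[1].strip()
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: bad GMT line: {line[:80]}")
                name, desc, genes = parts[0], parts[1], parts[2:]
                cats[name] = (desc, frozenset(g for g in genes if g))
        if release is None:
            raise ValueError(f"{path}: missing '#release <tag>' header")
        return cls(cats, release, source)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#release {self.release}\n")
            for name, (desc, genes) in self.categories.items():
                fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def ease_score(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """(ease_p, fisher_p) for k hits in a list of n, category size K,
    population N.

    fisher_p is the upper hypergeometric tail P(X >= k); ease_p repeats
    the computation with the hit cell reduced by one and all margins
    unchanged, so a category supported by a single gene scores 1.  The
    penalized tail is always the larger of the two.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    fisher_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    ease_p = 1.0 if k <= 1 else float(stats.hypergeom.sf(k - 2, N, K, n))
    return min(ease_p, 1.0), min(fisher_p, 1.0)


@dataclass
class EnrichmentResult:
    category: str
    description: str
    hits: int
    list_size: int
    category_size: int
    population_size: int
    ease_p: float
    fisher_p: float
    adjusted_q: float = float("nan")


def enrich(
    gene_list: Iterable[str],
    base_set: Iterable[str],
    category_db: CategoryDatabase,
    list_release: str | None = None,
    min_category_size: int = 2,
) -> pd.DataFrame:
    """Score every category against a gene list drawn from a base set.

    Categories are intersected with the base set first (a category gene
    never detected on the platform cannot be a hit or a miss); those
    smaller than ``min_category_size`` after intersection are skipped.
    Results are sorted by ease_p, with BH-adjusted q-values over the
    tested categories.
    """
    genes = set(gene_list)
    base = set(base_set)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= base:
        raise ValueError("gene list must be a subset of the base set (population)")
    if list_release is not None and list_release != category_db.release:
        raise ReleaseMismatchError(
            f"list is on {list_release} but categories on {category_db.release}; "
            "run refresh_categories first"
        )
    N, n = len(base), len(genes)
    rows = []
    for name, (desc, cat) in category_db.categories.items():
        cat_in_base = cat & base
        if len(cat_in_base) < min_category_size:
            continue
        k = len(cat_in_base & genes)
        ease_p, fisher_p = ease_score(k, n, len(cat_in_base), N)
        rows.append(
            EnrichmentResult(
                name, desc, k, n, len(cat_in_base), N, ease_p, fisher_p
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "category", "description", "hits", "list_size", "category_size",
                "population_size", "ease_p", "fisher_p", "adjusted_q",
            ]
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["adjusted_q"] = multipletests(df["ease_p"], method="fdr_bh")[1]
    return df.sort_values("ease_p", kind="stable").reset_index(drop=True)


def refresh_categories(
    category_db: CategoryDatabase,
    to_release: str,
    history: _lineage.ReleaseHistory,
) -> tuple[CategoryDatabase, list[str]]:
    """Bring every category's gene set up to a newer release.

    Each set is converted with the lineage converter: merged genes are
    deduplicated, split daughters join the category, killed genes are
    dropped with a log entry.  Categories left empty are flagged for
    removal (and excluded from the refreshed database).
    """
    change_log: list[str] = []
    new_cats: dict[str, tuple[str, frozenset[str]]] = {}
    for name, (desc, genes) in category_db.categories.items():
        try:
            converted, report = _lineage.convert_list(
                sorted(genes), category_db.release, to_release, history
            )
        except _lineage.LineageError as err:
            raise _lineage.LineageError(f"category {name!r}: {err}") from err
        for gene, rel in report.killed:
            change_log.append(f"{name}: {gene} killed at {rel}, dropped")
        for src, tgt in report.merged.items():
            change_log.append(f"{name}: {src} merged into {tgt}")
        for g in report.split_added:
            change_log.append(f"{name}: split daughter {g} added")
        for g in report.unresolved:
            change_log.append(f"{name}: {g} not found in {category_db.release}, dropped")
        if not converted:
            change_log.append(f"{name}: empty after conversion, flagged for removal")
            continue
        new_cats[name] = (desc, frozenset(converted))
    return (
        CategoryDatabase(new_cats, to_release, category_db.source),
        change_log,
    )
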