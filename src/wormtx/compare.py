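"""Cross-platform and cross-pathogen gene-set comparison.

All set algebra here operates on gene sets pinned to a single annotation
release: comparing lists annotated against different releases is the
classic source of silent errors this package exists to prevent, so every
operation refuses mixed-release inputs and directs the user to the
lineage converter first.

Includes platform base-set construction (the detected-gene universe per
technology), Venn region counting, shared/specific list extraction,
biomarker selection (multi-platform concordance and low-expression /
high-induction lists), peptide-length class analysis and conservation
enrichment, the latter two by Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class MixedReleaseError(ValueError):
    """Gene sets from different annotation releases cannot be compared
    directly; convert them to a common release first."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    release: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def _common_release(sets: Sequence[GeneSet]) -> str:
    releases = {s.release for s in sets}
    if len(releases) != 1:
        raise MixedReleaseError(
            f"gene sets span releases {sorted(releases)}; run the lineage "
            "converter to bring them to one release first"
        )
    return releases.pop()


@dataclass
class PlatformDataset:
    """One platform's detected-gene universe and its up/down calls."""

    platform: str
    release: str
    base_set: frozenset[str]
    up_set: frozenset[str] = frozenset()
    down_set: frozenset[str] = frozenset()

    def __post_init__(self):
        self.base_set = frozenset(self.base_set)
        self.up_set = frozenset(self.up_set)
        self.down_set = frozenset(self.down_set)
        if not self.up_set <= self.base_set or not self.down_set <= self.base_set:
            raise ValueError(f"{self.platform}: up/down sets must lie in the base set")
        if self.up_set & self.down_set:
            raise ValueError(f"{self.platform}: up and down sets overlap")


# ---------------------------------------------------------------------------
# platform base sets

@dataclass
class BaseSetRule:
    """Detection rule defining a platform's base set.

    oligo:  signal at least ``signal_factor`` times background and
            unflagged in at least ``min_arrays`` of ``n_arrays`` arrays
    cdna:   over ``psl_threshold`` PSL in either channel of at least one
            of two experiments
    rnaseq: non-zero dcpm in at least one dataset
    tiling: every transcript (tiling values are never exactly zero)
    """

    platform: str
    signal_factor: float = 2.0
    min_arrays: int = 4
    n_arrays: int = 6
    psl_threshold: float = 40.0

    def __post_init__(self):
        if self.platform not in ("oligo", "cdna", "rnaseq", "tiling"):
            raise ValueError(f"unknown platform {self.platform!r}")


def build_base_set(raw_platform_data, rule: BaseSetRule) -> frozenset[str]:
    """Apply a platform detection rule to raw data.

    Expected shapes: oligo — mapping with 'signal', 'background' and
    'flagged' DataFrames (genes x arrays); cdna — sequence of paired
    tables with transcript_id/control/infected in PSL; rnaseq — DataFrame
    of dcpm values (genes x datasets, NaN = missing); tiling — any
    iterable of gene ids.
    """
    p = rule.platform
    if p == "oligo":
        sig = raw_platform_data["signal"]
        bkg = raw_platform_data["background"]
        flg = raw_platform_data["flagged"].astype(bool)
        good = (sig.to_numpy() >= rule.signal_factor * bkg.to_numpy()) & ~flg.to_numpy()
        keep = good.sum(axis=1) >= rule.min_arrays
        return frozenset(np.asarray(sig.index)[keep].astype(str))
    if p == "cdna":
        detected: set[str] = set()
        for table in raw_platform_data:
            df = pd.DataFrame(table)
            hit = (df["control"] > rule.psl_threshold) | (
                df["infected"] > rule.psl_threshold
            )
            detected |= set(df.loc[hit, "transcript_id"].astype(str))
        return frozenset(detected)
    if p == "rnaseq":
        df = pd.DataFrame(raw_platform_data)
        vals = df.to_numpy(dtype=float)
        keep = np.nansum(np.nan_to_num(vals) != 0, axis=1) >= 1
        return frozenset(np.asarray(df.index)[keep].astype(str))
    # tiling
    return frozenset(str(g) for g in raw_platform_data)


# ---------------------------------------------------------------------------
# set algebra

@dataclass
class OverlapReport:
    set_names: list[str]
    regions: dict[frozenset[str], int]  # membership signature -> count
    pairwise: pd.DataFrame  # |A∩B| with % of A and % of B

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def venn_counts(sets: Sequence[GeneSet]) -> OverlapReport:
    """Counts for every region of a 2–5 set Venn diagram.

    Pairwise overlaps are reported as percentages of *both* sets, since a
    single "overlap %" is ambiguous about its denominator.
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError("venn_counts supports 2 to 5 sets")
    _common_release(sets)
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    union = set().union(*(s.genes for s in sets))
    regions: dict[frozenset[str], int] = {}
    for g in union:
        sig = frozenset(s.name for s in sets if g in s.genes)
        regions[sig] = regions.get(sig, 0) + 1
    rows = []
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            inter = len(a.genes & b.genes)
            rows.append(
                {
                    "set_a": a.name,
                    "set_b": b.name,
                    "intersection": inter,
                    "pct_of_a": 100.0 * inter / len(a.genes) if a.genes else np.nan,
                    "pct_of_b": 100.0 * inter / len(b.genes) if b.genes else np.nan,
                }
            )
    return OverlapReport(names, regions, pd.DataFrame(rows))


def shared_and_specific(
    datasets: Mapping[str, GeneSet],
    combinations: Mapping[str, tuple[Sequence[str], Sequence[str]]],
) -> dict[str, frozenset[str]]:
    """Evaluate declarative set combinations over named datasets.

    Each combination maps a label to (include, exclude): the result is
    the intersection of the included sets minus the union of the excluded
    ones, e.g. ("both fungi", ([dc, hs], [sm, ef, pl])).
    """
    if not combinations:
        raise ValueError("empty combination mapping")
    _common_release(list(datasets.values()))
    out: dict[str, frozenset[str]] = {}
    for label, (include, exclude) in combinations.items():
        if not include:
            raise ValueError(f"combination {label!r} includes no set")
        acc = set(datasets[include[0]].genes)
        for name in include[1:]:
            acc &= datasets[name].genes
        for name in exclude:
            acc -= datasets[name].genes
        out[label] = frozenset(acc)
    return out


# ---------------------------------------------------------------------------
# biomarkers

@dataclass
class BiomarkerCriteria:
    min_platforms: int = 2
    high_induction_fold: float = 20.0
    low_expression_quantile: float = 0.25

    def __post_init__(self):
        if self.min_platforms < 2:
            raise ValueError("min_platforms must be >= 2")
        if self.high_induction_fold <= 1:
            raise ValueError("fold threshold must exceed 1")


def select_biomarkers(
    platform_datasets: Sequence[PlatformDataset],
    expression_pairs: pd.DataFrame,
    criteria: BiomarkerCriteria | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Two biomarker lists for one infection.

    List 1: genes called up on at least ``min_platforms`` platforms — the
    high-confidence multi-technique catalogue.  List 2: genes whose
    uninfected baseline lies below the ``low_expression_quantile`` of the
    non-zero baselines yet which are induced more than
    ``high_induction_fold``-fold — lowly expressed genes that a
    concordance list biased to high expression would miss.
    ``expression_pairs`` supplies the baseline/infected values
    (transcript_id, control, infected), typically from RNA-seq.
    """
    criteria = criteria or BiomarkerCriteria()
    releases = {d.release for d in platform_datasets}
    if len(releases) > 1:
        raise MixedReleaseError(f"platform datasets span releases {sorted(releases)}")
    counts: dict[str, int] = {}
    for d in platform_datasets:
        for g in d.up_set:
            counts[g] = counts.get(g, 0) + 1
    list1 = frozenset(g for g, c in counts.items() if c >= criteria.min_platforms)

    df = pd.DataFrame(expression_pairs)
    base = df["control"].to_numpy(dtype=float)
    inf_v = df["infected"].to_numpy(dtype=float)
    nz = base[base > 0]
    if nz.size == 0:
        return list1, frozenset()
    low_cut = float(np.quantile(nz, criteria.low_expression_quantile))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(base > 0, inf_v / np.where(base > 0, base, 1.0), np.inf)
    fold = np.where((base == 0) & (inf_v == 0), 0.0, fold)
    keep = (base < low_cut) & (fold > criteria.high_induction_fold)
    list2 = frozenset(df.loc[keep, "transcript_id"].astype(str))
    return list1, list2


# ---------------------------------------------------------------------------
# peptide length classes

@dataclass
class PeptideLengthConfig:
    n_classes: int = 5
    short_cutoff_aa: int = 90
    equal_width: bool = False  # default: equal-count classes
    yates_correction: bool = False

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 length classes")


def peptide_length_analysis(
    up_sets_by_pathogen: Mapping[str, Iterable[str]],
    protein_lengths: Mapping[str, float] | pd.Series,
    config: PeptideLengthConfig | None = None,
    fungal: Sequence[str] = (),
    bacterial: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict | None]:
    """Distribution of encoded-protein lengths among induced genes.

    All proteins are divided into ``n_classes`` classes — by default
    equal-count classes of the genome-wide length distribution, so the
    reference list sits near ``100/n`` % in each class — and the per-list
    percentages are tabulated.  When fungal and bacterial list names are
    given, a 2x2 Pearson chi-square compares the frequency of short
    peptides (< ``short_cutoff_aa`` residues) between the two groups.
    Genes without a known protein length are excluded.
    """
    config = config or PeptideLengthConfig()
    lengths = pd.Series(protein_lengths, dtype=float).dropna()
    if lengths.empty:
        raise ValueError("no protein lengths available")
    qs = np.linspace(0, 100, config.n_classes + 1)[1:-1]
    if config.equal_width:
        bounds = np.linspace(lengths.min(), lengths.max(), config.n_classes + 1)[1:-1]
    else:
        bounds = np.percentile(lengths, qs, method="lower")
    def class_pcts(ids: Iterable[str]) -> np.ndarray:
        vals = lengths.reindex(list(ids)).dropna().to_numpy()
        if vals.size == 0:
            return np.full(config.n_classes, np.nan)
        # right-closed classes: (b0, b1], (b1, b2], ...
        idx = np.searchsorted(bounds, vals, side="left")
        counts = np.bincount(idx, minlength=config.n_classes)
        return 100.0 * counts / vals.size

    table = {"All": class_pcts(lengths.index)}
    for name, ids in up_sets_by_pathogen.items():
        table[name] = class_pcts(ids)
    edges = ["0", *(f"{b:.0f}" for b in bounds), "max"]
    cols = [f"({edges[i]}, {edges[i+1]}]" for i in range(config.n_classes)]
    freq = pd.DataFrame(table, index=cols).T

    test = None
    if fungal and bacterial:
        def short_counts(names: Sequence[str]) -> tuple[int, int]:
            ids = set()
            for n in names:
                ids |= set(up_sets_by_pathogen[n])
            vals = lengths.reindex(sorted(ids)).dropna()
            short = int((vals < config.short_cutoff_aa).sum())
            return short, len(vals) - short
        f_short, f_long = short_counts(fungal)
        b_short, b_long = short_counts(bacterial)
        obs = np.array([[f_short, f_long], [b_short, b_long]])
        chi2, p, dof, _ = stats.chi2_contingency(obs, correction=config.yates_correction)
        test = {
            "table": obs,
            "chi2": float(chi2),
            "p_value": float(p),
            "dof": int(dof),
            "fungal_short_pct": 100.0 * f_short / (f_short + f_long),
            "bacterial_short_pct": 100.0 * b_short / (b_short + b_long),
        }
    return freq, test


# ---------------------------------------------------------------------------
# conservation

def conservation_enrichment(
    up_set: Iterable[str],
    expressed_set: Iterable[str],
    conserved_set: Iterable[str],
    yates_correction: bool = False,
) -> dict:
    """Is the induced list depleted (or enriched) in conserved genes?

    Builds the 2x2 table (up, expressed-not-up) x (conserved, not) and
    applies the Pearson chi-square, reporting the conserved fraction of
    each row.  Rapidly evolving defense genes show up as depletion.
    """
    up = set(up_set)
    expressed = set(expressed_set)
    conserved = set(conserved_set)
    if not up:
        raise ValueError("empty up-regulated set")
    if not up <= expressed:
        raise ValueError("up-regulated set must be a subset of the expressed set")
    rest = expressed - up
    obs = np.array(
        [
            [len(up & conserved), len(up - conserved)],
            [len(rest & conserved), len(rest - conserved)],
        ]
    )
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=yates_correction)
    return {
        "table": obs,
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "up_conserved_pct": 100.0 * obs[0, 0] / obs[0].sum(),
        "expressed_conserved_pct": 100.0 * obs[1, 0] / obs[1].sum() if obs[1].sum() else float("nan"),
    }
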