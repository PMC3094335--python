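"""Synthetic data with known ground truth for every analysis module.

Three generators, all fully determined by an explicit seed:

* annotation histories — multi-release gene tables with merge, split,
  kill, create and rename events plus a truth map recording each initial
  gene's final fate, for exercising the lineage converter;
* paired expression tables — log-normal baselines with planted up/down
  fractions, heteroscedastic log-ratio noise that inflates at low
  expression (the property that makes naive fold-change calling
  unreliable for lowly expressed genes), and a zero-inflated
  infection-specific class;
* tiling probes and per-base coverage over transcript models, for
  checking the quantification pipelines against planted signals.

These emulate the *structure* of the real data (identifier churn,
mean–variance behaviour, platform layouts), not the quantitative gene
length or expression distributions of the C. elegans genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lineage import GeneRecord, LineageEvent, ReleaseHistory, ReleaseTag
from .quant import (
    CoverageTrack,
    GenomicInterval,
    ProbeMeasurement,
    ReadStats,
    TranscriptModel,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation histories

@dataclass
class HistorySimConfig:
    """Expected event counts are per release transition; counts are drawn
    Poisson and clamped to the genes actually available."""

    n_genes: int = 100
    n_releases: int = 4
    merge_rate: float = 2.0
    split_rate: float = 2.0
    kill_rate: float = 2.0
    create_rate: float = 2.0
    rename_rate: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_releases < 1:
            raise ValueError("need at least one gene and one release")
        for r in (self.merge_rate, self.split_rate, self.kill_rate,
                  self.create_rate, self.rename_rate):
            if r < 0:
                raise ValueError("event rates must be non-negative")


def _new_record(k: int, public: bool) -> GeneRecord:
    seq = f"SIM{k // 9 + 1:04d}.{k % 9 + 1}"
    return GeneRecord(
        wbid=f"WBGene{k + 1:08d}",
        sequence_name=seq,
        public_name=f"sim-{k + 1}" if public else "",
        transcript_names=(seq + "a",),
    )


def simulate_history(config: HistorySimConfig) -> tuple[ReleaseHistory, dict]:
    """Generate a release history plus a truth map.

    The truth map records, for every gene live in the first release, its
    fate at the last release: ``("live", final_wbid)`` or
    ``("dead", release_of_death)`` — exactly what a forward conversion of
    the initial identifier list must reproduce.
    """
    rng = np.random.default_rng(config.seed)
    releases = [ReleaseTag(ordinal=i, name=f"WS{150 + 10 * i}") for i in range(config.n_releases)]
    counter = 0
    table: dict[str, GeneRecord] = {}
    for _ in range(config.n_genes):
        rec = _new_record(counter, public=bool(rng.random() < 0.3))
        table[rec.wbid] = rec
        counter += 1
    tables = {releases[0].name: dict(table)}
    events: list[LineageEvent] = []

    initial = list(table)
    current: dict[str, str | None] = {w: w for w in initial}  # initial -> live id
    death: dict[str, str] = {}

    for tag in releases[1:]:
        live = [w for w, r in table.items() if r.status == "live"]
        touched: set[str] = set()

        def draw(rate: float) -> int:
            return int(rng.poisson(rate))

        def pick(n: int) -> list[str]:
            avail = [w for w in live if w not in touched]
            n = min(n, len(avail))
            chosen = list(rng.choice(avail, size=n, replace=False)) if n else []
            touched.update(chosen)
            return chosen

        # merges
        for _ in range(draw(config.merge_rate)):
            pair = pick(2)
            if len(pair) < 2:
                break
            survivor = pair[int(rng.integers(2))]
            ev = LineageEvent(tag.name, "merge", tuple(sorted(pair)), (survivor,))
            events.append(ev)
            for w in pair:
                if w != survivor:
                    table[w] = GeneRecord(
                        wbid=w, sequence_name=table[w].sequence_name,
                        public_name=table[w].public_name,
                        transcript_names=(), status="dead",
                    )
            for ini, cur in current.items():
                if cur in pair:
                    current[ini] = survivor
        # splits: parent retained, one or two new daughters
        for _ in range(draw(config.split_rate)):
            parent = pick(1)
            if not parent:
                break
            parent = parent[0]
            n_new = int(rng.integers(1, 3))
            daughters = []
            for _ in range(n_new):
                rec = _new_record(counter, public=False)
                counter += 1
                table[rec.wbid] = rec
                daughters.append(rec.wbid)
            events.append(
                LineageEvent(tag.name, "split", (parent,), (parent, *daughters))
            )
        # kills
        n_kill = draw(config.kill_rate)
        victims = pick(n_kill)
        if len(victims) < n_kill:
            logger.warning(
                "%s: kill count clamped from %d to %d (not enough live genes)",
                tag.name, n_kill, len(victims),
            )
        for w in victims:
            events.append(LineageEvent(tag.name, "kill", (w,), ()))
            table[w] = GeneRecord(
                wbid=w, sequence_name=table[w].sequence_name,
                public_name=table[w].public_name, transcript_names=(), status="dead",
            )
            for ini, cur in current.items():
                if cur == w:
                    current[ini] = None
                    death[ini] = tag.name
        # creations
        for _ in range(draw(config.create_rate)):
            rec = _new_record(counter, public=bool(rng.random() < 0.3))
            counter += 1
            table[rec.wbid] = rec
            events.append(LineageEvent(tag.name, "create", (), (rec.wbid,)))
        # renames: wbid kept, names change
        for w in pick(draw(config.rename_rate)):
            old = table[w]
            new_seq = f"REN{counter:05d}.1"
            counter += 1
            table[w] = GeneRecord(
                wbid=w, sequence_name=new_seq,
                public_name=old.public_name, transcript_names=(new_seq + "a",),
            )
            events.append(LineageEvent(tag.name, "rename", (w,), (w,)))
        tables[tag.name] = dict(table)

    truth = {
        ini: (("dead", death[ini]) if current[ini] is None else ("live", current[ini]))
        for ini in initial
    }
    hist = ReleaseHistory(releases=releases, tables=tables, events=events)
    return hist, truth


# ---------------------------------------------------------------------------
# paired expression tables

@dataclass
class ExpressionSimConfig:
    """Paired (uninfected, infected) expression with planted regulation.

    Each transcript has a true abundance t drawn log-normal (natural-log
    mean/sd of the underlying normal).  Both conditions are *measured*
    values: control = t * 2^e1 and infected = t * fold * 2^e2, where e1
    and e2 are independent N(0, s0 + s1/(t+1)) — the minimal model in
    which each measurement's relative variation grows as expression
    falls, so the log ratio fans out at low expression on both sides of
    the diagonal.  fold is the planted induction/repression factor (1 for
    null transcripts).  A small zero-inflated class is expressed only
    after infection.
    """

    n_transcripts: int = 5000
    baseline_log_mean: float = 1.6
    baseline_log_sd: float = 1.5
    up_fraction: float = 0.05
    up_fold: float = 4.0
    down_fraction: float = 0.05
    down_fold: float = 4.0
    noise_s0: float = 0.1
    noise_s1: float = 1.5
    zero_inflation: float = 0.01
    seed: int = 0

    def __post_init__(self):
        total = self.up_fraction + self.down_fraction + self.zero_inflation
        if not (0 <= self.up_fraction <= 1 and 0 <= self.down_fraction <= 1 and total <= 1):
            raise ValueError("planted fractions must lie in [0,1] and sum <= 1")
        if self.up_fold <= 1 or self.down_fold <= 1:
            raise ValueError("planted folds must exceed 1")


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Return (paired table, truth labels).

    Labels are 'up', 'down', 'null' or 'infection_specific'.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = [f"T{k:06d}" for k in range(n)]
    true_level = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    labels = np.full(n, "null", dtype=object)
    perm = rng.permutation(n)
    n_up = int(round(config.up_fraction * n))
    n_down = int(round(config.down_fraction * n))
    n_zero = int(round(config.zero_inflation * n))
    labels[perm[:n_up]] = "up"
    labels[perm[n_up:n_up + n_down]] = "down"
    labels[perm[n_up + n_down:n_up + n_down + n_zero]] = "infection_specific"

    sd = config.noise_s0 + config.noise_s1 / (true_level + 1.0)
    e1 = rng.normal(0.0, 1.0, size=n) * sd
    e2 = rng.normal(0.0, 1.0, size=n) * sd
    shift = np.where(
        labels == "up",
        math.log2(config.up_fold),
        np.where(labels == "down", -math.log2(config.down_fold), 0.0),
    )
    control = true_level * np.exp2(e1)
    infected = true_level * np.exp2(shift + e2)

    zi = labels == "infection_specific"
    control[zi] = 0.0
    infected[zi] = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=int(zi.sum()))

    table = pd.DataFrame(
        {"transcript_id": ids, "control": control, "infected": infected}
    )
    return table, pd.Series(labels, index=ids, name="label")


# ---------------------------------------------------------------------------
# probes and coverage

@dataclass
class PlatformSimConfig:
    """Tiling probes and RNA-seq coverage consistent with one expression
    vector, so both quantification pipelines can be checked against the
    same planted truth."""

    probe_length: int = 25
    probe_step: int = 25
    n_replicates: int = 2
    mm_fraction: float = 0.3  # mismatch probes capture this fraction of signal
    noise_sd: float = 0.0
    mapped_reads: int = 1_000_000
    representation_cutoff: int = 96
    high_representation_transcripts: tuple[str, ...] = ()
    seed: int = 0


def make_transcript_models(
    n_transcripts: int = 20,
    exons_per_transcript: int = 2,
    exon_length: int = 200,
    intron_length: int = 100,
    gap: int = 500,
    chrom: str = "chrI",
) -> list[TranscriptModel]:
    """Regularly spaced multi-exon models on one chromosome."""
    models = []
    pos = 0
    for t in range(n_transcripts):
        exons = []
        for _ in range(exons_per_transcript):
            exons.append(GenomicInterval(chrom, pos, pos + exon_length))
            pos += exon_length + intron_length
        pos += gap
        models.append(
            TranscriptModel(
                transcript_id=f"T{t:04d}.1", gene_id=f"G{t:04d}", exons=exons
            )
        )
    return models


def simulate_probes_and_coverage(
    models: Sequence[TranscriptModel],
    expression: Mapping[str, float],
    config: PlatformSimConfig,
) -> tuple[list[ProbeMeasurement], CoverageTrack, ReadStats]:
    """Probes tiling each transcript's exons and matching base coverage.

    Probe PM intensity is the transcript's expression value plus noise;
    MM is a fixed fraction of PM plus noise.  Coverage depth on every
    exonic base equals the expression value, so dcpm should recover
    ``expr * 1e6 / mapped_reads``.  Bases of transcripts listed in
    ``high_representation_transcripts`` are planted at the representation
    cutoff and therefore drop out of the dcpm denominator.
    """
    rng = np.random.default_rng(config.seed)
    probes: list[ProbeMeasurement] = []
    cov_rows = []
    for m in models:
        e = float(expression[m.transcript_id])
        high_rep = m.transcript_id in config.high_representation_transcripts
        rep = config.representation_cutoff if high_rep else 1
        for exon in m.exons:
            for start in range(exon.start, exon.end - config.probe_length + 1, config.probe_step):
                pm = e + rng.normal(0, config.noise_sd, config.n_replicates)
                mm = config.mm_fraction * pm + rng.normal(
                    0, config.noise_sd, config.n_replicates
                )
                probes.append(
                    ProbeMeasurement(
                        probe_id=f"{m.transcript_id}:{start}",
                        interval=GenomicInterval(exon.chrom, start, start + config.probe_length),
                        pm=pm,
                        mm=mm,
                    )
                )
            for pos in range(exon.start, exon.end):
                if e > 0 or high_rep:
                    cov_rows.append((exon.chrom, pos, e, rep))
    cov = pd.DataFrame(
        cov_rows, columns=["chrom", "pos", "score", "representation"]
    )
    if cov.empty:
        cov = pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int),
             "score": pd.Series(dtype=float), "representation": pd.Series(dtype=int)}
        )
    return probes, CoverageTrack(cov), ReadStats(config.mapped_reads)
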