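"""Count-matrix preparation, DEG classification and knockdown-overlap logic.

This module prepares gene-level RNA-seq count matrices for differential
expression and post-processes DE results; the DE engine itself (size-factor
normalisation, dispersion shrinkage, LRT/Wald testing) is delegated — any
results table with ``gene_id``/``log2fc``/``fdr`` columns is accepted.

Pipeline order is fixed: PAR_Y collapsing first, then the pre-filters
(low-expression: row total < 2 x number of samples; short transcripts:
average length <= 20 bp). DEG significance is strict on both sides:
|log2FC| > 1 and FDR < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

PAR_Y_SUFFIX = "_PAR_Y"
#: low-expression rule: drop genes with total counts < 2 x number of samples
LOW_COUNT_FACTOR = 2
#: short-transcript rule: drop genes with average transcript length <= 20 bp
MIN_TRANSCRIPT_LENGTH = 20.0
#: DEG thresholds: |log2FC| > 1 and FDR < 0.01, both strict
DEFAULT_LFC_CUT = 1.0
DEFAULT_FDR_CUT = 0.01


@dataclass
class CountMatrix:
    """Gene-level counts with per-gene transcript lengths and sample groups.

    ``counts`` is genes x samples (non-negative integers, gene ids as index);
    ``transcript_lengths`` holds the per-gene average transcript length in bp;
    ``sample_groups`` maps sample id to treatment group. ``prefiltered``
    records whether the pre-filters have run (PAR_Y collapsing must precede
    them, and :func:`prefilter_counts` enforces the order).
    """

    counts: pd.DataFrame
    transcript_lengths: pd.Series
    sample_groups: Optional[pd.Series] = None
    collapsed: bool = False
    prefiltered: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates and not self._only_par_y_dups():
            raise ValueError("duplicate gene ids beyond PAR_Y pairs")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.transcript_lengths.index.equals(self.counts.index):
            missing = self.counts.index.difference(self.transcript_lengths.index)
            if len(missing):
                raise ValueError(f"missing transcript lengths for {len(missing)} genes")
            self.transcript_lengths = self.transcript_lengths.reindex(self.counts.index)
        if self.sample_groups is not None and not self.sample_groups.index.equals(
            self.counts.columns
        ):
            raise ValueError("sample_groups index must match count columns")

    def _only_par_y_dups(self) -> bool:
        dups = self.counts.index[self.counts.index.duplicated()]
        return all(d.endswith(PAR_Y_SUFFIX) for d in dups)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def collapse_par_y(matrix: CountMatrix) -> CountMatrix:
    """Merge pseudoautosomal Y-chromosome gene copies into their base ids.

    Every gene id ending in ``_PAR_Y`` loses the suffix; when the renamed id
    collides with an existing gene, the two count rows are summed
    element-wise and the merged transcript length is the count-weighted mean
    of the two (preserving the semantics of the length filter; ties on zero
    total counts fall back to the unweighted mean).
    """
    idx = matrix.counts.index
    stripped = pd.Index(
        [g[: -len(PAR_Y_SUFFIX)] if g.endswith(PAR_Y_SUFFIX) else g for g in idx]
    )
    counts = matrix.counts.copy()
    counts.index = stripped
    lengths = matrix.transcript_lengths.copy()
    lengths.index = stripped
    if stripped.has_duplicates:
        totals = counts.sum(axis=1)
        weights = totals.groupby(level=0).transform(
            lambda t: t / t.sum() if t.sum() > 0 else np.full(len(t), 1.0 / len(t))
        )
        lengths = (lengths * weights).groupby(level=0).sum()
        counts = counts.groupby(level=0, sort=False).sum()
        lengths = lengths.reindex(counts.index)
    return CountMatrix(
        counts=counts,
        transcript_lengths=lengths,
        sample_groups=matrix.sample_groups,
        collapsed=True,
    )


@dataclass
class PrefilterReport:
    """Counts of genes dropped by each pre-filter rule."""

    n_low_count: int
    n_short_transcript: int
    n_kept: int


def prefilter_counts(
    matrix: CountMatrix, return_report: bool = False
) -> CountMatrix | tuple[CountMatrix, PrefilterReport]:
    """Drop low-expression and short-transcript genes prior to DE analysis.

    A gene is dropped when its row total is strictly below
    ``2 x n_samples`` (a total of exactly ``2n`` survives) or when its
    average transcript length is <= 20 bp (inclusive; mostly short
    non-coding RNAs). Requires PAR_Y collapsing to have run first so that
    merged rows are filtered on their summed counts.
    """
    if not matrix.collapsed:
        raise ValueError(
            "prefilter_counts requires collapse_par_y to run first "
            "(merged PAR_Y rows must be filtered on summed counts)"
        )
    totals = matrix.counts.sum(axis=1)
    low = totals < LOW_COUNT_FACTOR * matrix.n_samples
    short = matrix.transcript_lengths <= MIN_TRANSCRIPT_LENGTH
    keep = ~(low | short)
    filtered = CountMatrix(
        counts=matrix.counts.loc[keep],
        transcript_lengths=matrix.transcript_lengths.loc[keep],
        sample_groups=matrix.sample_groups,
        collapsed=True,
        prefiltered=True,
    )
    if not return_report:
        return filtered
    report = PrefilterReport(
        n_low_count=int(low.sum()),
        n_short_transcript=int(short.sum()),
        n_kept=int(keep.sum()),
    )
    return filtered, report


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression call under the strict thresholds."""

    gene_id: str
    log2fc: float
    fdr: float
    direction: str  # "up" | "down"
    significant: bool


def classify_degs(
    results: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    fdr_cut: float = DEFAULT_FDR_CUT,
) -> list[DEGRecord]:
    """Apply the DEG significance rule to a delegated DE results table.

    ``results`` needs columns ``gene_id``, ``log2fc``, ``fdr``. Significant
    iff ``|log2fc| > lfc_cut`` and ``fdr < fdr_cut`` (both strict; a gene at
    exactly log2FC = 1 or FDR = 0.01 is not called). Direction is the sign
    of the fold change.
    """
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    fdr = results["fdr"].to_numpy(dtype=float)
    if np.any((fdr < 0) | (fdr > 1)):
        raise ValueError("fdr values must lie in [0, 1]")
    records = []
    for row in results.itertuples(index=False):
        lfc = float(row.log2fc)
        records.append(
            DEGRecord(
                gene_id=str(row.gene_id),
                log2fc=lfc,
                fdr=float(row.fdr),
                direction="up" if lfc > 0 else "down",
                significant=bool(abs(lfc) > lfc_cut and float(row.fdr) < fdr_cut),
            )
        )
    return records


@dataclass
class OverlapSummary:
    """Per-direction DEG set sizes and intersections between two conditions.

    Genes significant in opposite directions in the two conditions are
    counted in neither common set; they are reported in ``discordant``.
    """

    up_a: set = field(default_factory=set)
    up_b: set = field(default_factory=set)
    down_a: set = field(default_factory=set)
    down_b: set = field(default_factory=set)
    common_up: set = field(default_factory=set)
    common_down: set = field(default_factory=set)
    discordant: set = field(default_factory=set)

    @property
    def sizes(self) -> dict:
        return {
            "up_a": len(self.up_a), "up_b": len(self.up_b),
            "down_a": len(self.down_a), "down_b": len(self.down_b),
            "common_up": len(self.common_up), "common_down": len(self.common_down),
            "discordant": len(self.discordant),
        }

    def to_json_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "members": {
                k: sorted(getattr(self, k))
                for k in ("common_up", "common_down", "discordant")
            },
        }


def _direction_sets(records: Iterable[DEGRecord]) -> tuple[set, set]:
    records = list(records)
    ids = [r.gene_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids within one DEG list")
    up = {r.gene_id for r in records if r.significant and r.direction == "up"}
    down = {r.gene_id for r in records if r.significant and r.direction == "down"}
    return up, down


def overlap_degs(a: Iterable[DEGRecord], b: Iterable[DEGRecord]) -> OverlapSummary:
    """Per-direction intersection of two DEG lists (Venn logic).

    The common up (down) set contains genes significantly up (down) in both
    conditions; genes significant in opposite directions are excluded from
    both common sets and listed as discordant.
    """
    up_a, down_a = _direction_sets(a)
    up_b, down_b = _direction_sets(b)
    discordant = (up_a & down_b) | (down_a & up_b)
    return OverlapSummary(
        up_a=up_a, up_b=up_b, down_a=down_a, down_b=down_b,
        common_up=(up_a & up_b) - discordant,
        common_down=(down_a & down_b) - discordant,
        discordant=discordant,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_matrix(counts_path, lengths_path, groups_path=None) -> CountMatrix:
    """Read a genes x samples TSV (first column gene id) plus a lengths TSV.

    The lengths TSV has columns ``gene_id`` and ``length``; the optional
    groups TSV has ``sample`` and ``group``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    groups = None
    if groups_path is not None:
        groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(
        counts=counts.astype(np.int64),
        transcript_lengths=lengths.astype(float),
        sample_groups=groups,
    )


def write_count_matrix(matrix: CountMatrix, counts_path, lengths_path, groups_path=None):
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.transcript_lengths.rename("length").to_csv(
        lengths_path, sep="\t", index_label="gene_id"
    )
    if groups_path is not None and matrix.sample_groups is not None:
        matrix.sample_groups.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample"
        )


def run_default_de_engine(
    matrix: CountMatrix, treated: str = "treated", control: str = "control"
) -> pd.DataFrame:
    """Delegated differential-expression engine (DESeq2 via pydeseq2).

    Convenience adapter producing the ``gene_id``/``log2fc``/``fdr`` table
    that :func:`classify_degs` consumes; any other engine writing the same
    columns is equally valid (the module does not depend on this one).
    Requires the optional ``pydeseq2`` dependency.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    if matrix.sample_groups is None:
        raise ValueError("matrix has no sample_groups")
    metadata = pd.DataFrame(
        {"condition": matrix.sample_groups.values}, index=matrix.counts.columns
    )
    dds = DeseqDataSet(
        counts=matrix.counts.T, metadata=metadata, design="~condition", quiet=True
    )
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", treated, control], quiet=True)
    ds.summary()
    res = ds.results_df
    return pd.DataFrame(
        {
            "gene_id": res.index,
            "log2fc": res["log2FoldChange"].to_numpy(),
            "fdr": res["padj"].fillna(1.0).to_numpy(),
        }
    ).reset_index(drop=True)


def read_de_results(path) -> pd.DataFrame:
    """Read a delegated DE results TSV with gene_id/log2fc/fdr columns."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "fdr"} - set(frame.columns)
    if missing:
        raise ValueError(f"DE results file missing columns: {sorted(missing)}")
    return frame
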