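"""Methylation metaprofiles around translation start/end sites and windowed
gene/repeat density correlation.

Metaprofiles average per-cytosine methylation levels in 5 nt bins over a
+/- 500 nt flank around the representative isoform's CDS endpoints,
separately per sequence context (CG/CHG/CHH) and per gene class; offsets
are computed in transcription orientation, so minus-strand genes are
flipped.  Density tracks count features per 1 Mb window by start position
and are compared with Spearman rank correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gffio import GeneModel, GenomeSequence, Interval, ValidationError

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
ANCHORS = ("translation_start", "translation_end")
FLANK = 500
BIN_WIDTH = 5
WINDOW_BP = 1_000_000

METHYLATION_COLUMNS = ["chrom", "pos", "strand", "context",
                       "n_methylated", "n_total"]


@dataclass(frozen=True)
class MethylationCall:
    chrom: str
    pos: int
    strand: str
    context: str
    n_methylated: int
    n_total: int

    @property
    def level(self) -> float:
        return self.n_methylated / self.n_total


@dataclass
class MetaProfile:
    """Mean methylation level per 5 nt offset bin around one anchor for one
    (gene class, context) stratum.  Bins with no cytosines are NaN."""

    anchor: str
    context: str
    gene_class: str
    offsets: np.ndarray      # left edge of each bin, -500 .. +495
    mean_level: np.ndarray   # NaN where n == 0
    n_cytosines: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor": self.anchor, "context": self.context,
            "gene_class": self.gene_class, "offset": self.offsets,
            "mean_level": self.mean_level, "n_cytosines": self.n_cytosines,
        })


def read_methylation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METHYLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"methylation table missing columns {missing}")
    if (df["n_total"] < 1).any() or (df["n_methylated"] > df["n_total"]).any():
        raise ValidationError("invalid methylation counts")
    return df


def _anchor_position(transcript, anchor: str) -> int | None:
    if anchor == "translation_start":
        return transcript.cds_start
    if anchor == "translation_end":
        return transcript.cds_stop
    raise ValueError(f"unknown anchor {anchor!r}")


def methylation_metaprofile(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = FLANK,
    bin_width: int = BIN_WIDTH,
    anchors: tuple[str, ...] = ANCHORS,
    contexts: tuple[str, ...] = CONTEXTS,
) -> list[MetaProfile]:
    """Per (class, context, anchor) mean methylation in *bin_width* nt bins
    over [-flank, +flank) around the representative isoform's CDS endpoints.

    Genes without a class, a representative, or a CDS are skipped with a
    warning.  The per-bin value is the unweighted mean of per-cytosine
    levels pooled over genes of the class.
    """
    n_bins = 2 * flank // bin_width
    offsets = np.arange(-flank, flank, bin_width)
    level = calls["n_methylated"].to_numpy() / calls["n_total"].to_numpy()
    pos = calls["pos"].to_numpy()
    ctx = calls["context"].to_numpy()
    chrom_arr = calls["chrom"].to_numpy()

    # per-chromosome position-sorted views for fast range extraction
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom_arr):
        m = chrom_arr == c
        order = np.argsort(pos[m], kind="stable")
        per_chrom[c] = (pos[m][order], level[m][order], ctx[m][order])

    sums: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, np.ndarray] = {}

    def stratum(key):
        if key not in sums:
            sums[key] = np.zeros(n_bins)
            counts[key] = np.zeros(n_bins, dtype=int)
        return sums[key], counts[key]

    for g in genes:
        if g.gene_class is None or g.representative is None:
            logger.warning("gene %s lacks class/representative; skipped", g.gene_id)
            continue
        rep = g.get(g.representative)
        if not rep.cds:
            logger.warning("gene %s representative has no CDS; skipped", g.gene_id)
            continue
        if rep.chrom not in per_chrom:
            continue
        cpos, clev, cctx = per_chrom[rep.chrom]
        for anchor in anchors:
            a = _anchor_position(rep, anchor)
            lo, hi = a - flank, a + flank
            i, j = np.searchsorted(cpos, [lo, hi])
            if i == j:
                continue
            p, lv, cx = cpos[i:j], clev[i:j], cctx[i:j]
            off = (p - a) if rep.strand != "-" else (a - p)
            inside = (off >= -flank) & (off < flank)
            bins = (off[inside] + flank) // bin_width
            for context in contexts:
                cm = cx[inside] == context
                if not cm.any():
                    continue
                s, n = stratum((g.gene_class, context, anchor))
                np.add.at(s, bins[cm], lv[inside][cm])
                np.add.at(n, bins[cm], 1)

    profiles = []
    for (gene_class, context, anchor), s in sorted(sums.items()):
        n = counts[(gene_class, context, anchor)]
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        profiles.append(MetaProfile(anchor, context, gene_class,
                                    offsets.copy(), mean, n.copy()))
    return profiles


def profiles_to_frame(profiles: list[MetaProfile]) -> pd.DataFrame:
    if not profiles:
        return pd.DataFrame(columns=["anchor", "context", "gene_class",
                                     "offset", "mean_level", "n_cytosines"])
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


# ---------------------------------------------------------------------------
# window densities
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    window_bp: int
    counts: dict[str, np.ndarray]  # chrom -> per-window feature counts

    def flat(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))


def window_density(
    features: list[Interval],
    genome: GenomeSequence | dict[str, int],
    window_bp: int = WINDOW_BP,
) -> DensityTrack:
    """Count features per tiling window, assigning each feature to the
    window containing its start; the last window of a chromosome may be
    short."""
    lengths = genome.lengths() if isinstance(genome, GenomeSequence) else dict(genome)
    counts = {c: np.zeros(max(1, math.ceil(ln / window_bp)), dtype=int)
              for c, ln in lengths.items()}
    for f in features:
        if f.chrom not in lengths:
            raise ValidationError(f"feature on unknown chromosome {f.chrom}")
        if f.start >= lengths[f.chrom]:
            raise ValidationError(
                f"feature start {f.start} beyond end of {f.chrom}")
        counts[f.chrom][f.start // window_bp] += 1
    return DensityTrack(window_bp, counts)


def density_correlation(track_a: DensityTrack, track_b: DensityTrack
                        ) -> tuple[float, int]:
    """Genome-wide Spearman rank correlation over paired windows (average
    ranks on ties).  Returns (rho, n windows)."""
    if track_a.window_bp != track_b.window_bp or \
            sorted(track_a.counts) != sorted(track_b.counts) or \
            any(len(track_a.counts[c]) != len(track_b.counts[c])
                for c in track_a.counts):
        raise ValidationError("density tracks use different windowings")
    a, b = track_a.flat(), track_b.flat()
    if len(a) < 3:
        raise ValidationError("need at least 3 windows for a correlation")
    rho = stats.spearmanr(a, b).statistic
    return float(rho), len(a)
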