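"""Promoter CpG-density scoring and CpG-island classification.

The density statistic is the classical observed/expected CpG ratio over a
window of length L:

    ratio = n_CpG * L / (n_C * n_G)

where ``n_CpG`` counts overlapping CG dinucleotides on the given strand and
``n_C``/``n_G`` are mononucleotide counts.  A promoter is called a CpG island
(CGI) when ratio > 0.6, strictly; the ratio criterion alone is used — no
additional GC-percent or minimum-length condition is applied.  The statistic
is strand-symmetric (CG is its own reverse complement; C and G counts swap),
so either strand gives the same ratio.

Quartile binning of a cohort's ratios (Q1 = most CpG-poor quarter) is the
stratification variable for the inducibility analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError, UndefinedDensityError

#: strict lower bound of the observed/expected ratio defining a CpG island
CGI_RATIO_THRESHOLD = 0.6

#: a window with more than this fraction of N is reported as undefined
MAX_N_FRACTION = 0.5

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class PromoterWindow:
    """A TSS-anchored promoter window on a genome.

    ``upstream``/``downstream`` are non-negative extents in bp; the extracted
    window always has length ``upstream + downstream`` and reads 5'->3' on the
    gene's own strand.
    """

    gene: str
    chrom: str
    tss: int
    strand: str
    upstream: int
    downstream: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.upstream < 0 or self.downstream < 0:
            raise InputError("window extents must be non-negative")
        if self.upstream == 0 and self.downstream == 0:
            raise InputError("window must have positive length")


@dataclass(frozen=True)
class CpGDensity:
    """CpG counts and observed/expected ratio for one window."""

    n_cpg: int
    n_c: int
    n_g: int
    length: int

    @property
    def ratio(self) -> float:
        """Observed/expected CpG ratio; 0 by convention when n_C*n_G == 0."""
        denom = self.n_c * self.n_g
        if denom == 0:
            return 0.0
        return self.n_cpg * self.length / denom


def extract_promoter(genome: Mapping[str, str], window: PromoterWindow) -> str:
    """Slice a promoter window out of a genome (dict of chrom -> sequence).

    For a + strand gene the window is ``[tss - upstream, tss + downstream)``;
    for a − strand gene it is the reverse complement of
    ``[tss - downstream, tss + upstream)``, so that the returned sequence is
    always promoter-upstream-first on the gene's strand.
    """
    if window.chrom not in genome:
        raise InputError(f"unknown chromosome {window.chrom!r} for gene {window.gene!r}")
    chrom_seq = str(genome[window.chrom])
    if window.strand == "+":
        start = window.tss - window.upstream
        end = window.tss + window.downstream
    else:
        start = window.tss - window.downstream
        end = window.tss + window.upstream
    if start < 0 or end > len(chrom_seq):
        raise InputError(
            f"window [{start}, {end}) for gene {window.gene!r} is outside "
            f"{window.chrom!r} bounds [0, {len(chrom_seq)})"
        )
    segment = chrom_seq[start:end]
    if window.strand == "-":
        segment = str(Seq(segment).reverse_complement())
    return segment


def cpg_obs_exp_ratio(sequence: str) -> CpGDensity:
    """Count CpGs and compute the observed/expected ratio for one sequence.

    Ns are excluded from the C/G counts and from the length, and an N breaks
    a CG dinucleotide.  Empty, all-N, or mostly-N (>50%) input is reported as
    undefined rather than scored.
    """
    seq = sequence.upper()
    if not seq:
        raise UndefinedDensityError("empty sequence")
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = {b"A", b"C", b"G", b"T", b"N"}
    if not set(np.unique(arr)) <= valid:
        bad = set(np.unique(arr)) - valid
        raise InputError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    n_n = int(np.count_nonzero(arr == b"N"))
    length = arr.size - n_n
    if length == 0 or n_n / arr.size > MAX_N_FRACTION:
        raise UndefinedDensityError(
            f"density undefined: {n_n}/{arr.size} bases are N"
        )
    n_c = int(np.count_nonzero(arr == b"C"))
    n_g = int(np.count_nonzero(arr == b"G"))
    n_cpg = int(np.count_nonzero((arr[:-1] == b"C") & (arr[1:] == b"G")))
    return CpGDensity(n_cpg=n_cpg, n_c=n_c, n_g=n_g, length=length)


def classify_cgi(density: CpGDensity) -> str:
    """Return ``"CGI"`` iff ratio > 0.6 strictly, else ``"CpG-poor"``."""
    return "CGI" if density.ratio > CGI_RATIO_THRESHOLD else "CpG-poor"


def quartile_bins(ratios: Iterable[float] | pd.Series) -> pd.Series:
    """Assign each gene to a CpG-ratio quartile Q1 (lowest) .. Q4 (highest).

    Cut points are the empirical 25/50/75 percentiles (linear interpolation);
    a value equal to a cut point goes to the lower quartile.  Constant input
    yields all-Q1 with a warning.  Fewer than 4 finite values is an error.
    """
    series = pd.Series(ratios, dtype=float)
    values = series.to_numpy()
    if np.sum(np.isfinite(values)) < 4:
        raise InputError("quartile binning needs at least 4 finite values")
    q25, q50, q75 = np.percentile(values[np.isfinite(values)], [25, 50, 75])
    if q25 == q75:
        warnings.warn("constant CpG ratios: all genes assigned to Q1", stacklevel=2)
        return pd.Series(["Q1"] * len(series), index=series.index)
    labels = np.full(len(series), "Q4", dtype=object)
    labels[values <= q75] = "Q3"
    labels[values <= q50] = "Q2"
    labels[values <= q25] = "Q1"
    labels[~np.isfinite(values)] = None
    return pd.Series(labels, index=series.index)


def score_promoters(
    genome: Mapping[str, str], windows: Iterable[PromoterWindow]
) -> pd.DataFrame:
    """Score many promoter windows; one row per gene.

    Windows whose density is undefined (mostly N) get NaN ratio and no class.
    Emits both the raw CpG count and the length-normalised count per kb.
    """
    rows = []
    for win in windows:
        seq = extract_promoter(genome, win)
        try:
            dens = cpg_obs_exp_ratio(seq)
        except UndefinedDensityError:
            rows.append(
                {"gene": win.gene, "n_cpg": np.nan, "n_c": np.nan, "n_g": np.nan,
                 "length": np.nan, "cpg_per_kb": np.nan, "ratio": np.nan,
                 "cgi_class": None}
            )
            continue
        rows.append(
            {
                "gene": win.gene,
                "n_cpg": dens.n_cpg,
                "n_c": dens.n_c,
                "n_g": dens.n_g,
                "length": dens.length,
                "cpg_per_kb": 1000.0 * dens.n_cpg / dens.length,
                "ratio": dens.ratio,
                "cgi_class": classify_cgi(dens),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    finite = table["ratio"].notna()
    if finite.sum() >= 4:
        table.loc[finite, "quartile"] = quartile_bins(table.loc[finite, "ratio"])
    return table
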