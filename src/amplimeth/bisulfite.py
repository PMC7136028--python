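"""Clone-level bisulfite methylation quantification.

Bisulfite treatment converts unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine stays C.  Sequencing individual cloned amplicons
therefore gives a per-molecule methylation pattern: at each CpG, a retained
C means methylated, a T means unmethylated.  This module aligns clone reads
to an unconverted reference amplicon with a bisulfite-aware asymmetric
scoring scheme (reference C against read T is a match, never the reverse),
computes per-clone conversion-efficiency QC from non-CpG cytosines, calls
per-CpG methylation, assigns reads to alleles at a CpG-destroying promoter
SNP, and aggregates clone calls into per-CpG methylation profiles — overall
and allele-resolved.

Coordinates are 0-based half-open on the amplicon strand; CpG sites are
reported under TSS-relative labels (e.g. "-286") carried by the reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import (
    AlleleMissingError,
    EmptyProfileError,
    InputError,
    UndefinedEfficiencyError,
)

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MIN_INFORMATIVE = 3


# ---------------------------------------------------------------------------
# reference model


@dataclass(frozen=True)
class AmpliconSNP:
    """A single-base C/A polymorphism inside the amplicon.

    The C allele completes a CpG dinucleotide (methylatable); the A allele
    destroys it.  ``offset`` is 0-based on the amplicon strand and must
    coincide with a position listed in ``ReferenceAmplicon.cpg_positions``.
    """

    offset: int
    alleles: tuple[str, str] = ("C", "A")
    label: str = ""


@dataclass(frozen=True)
class ReferenceAmplicon:
    """An unconverted reference amplicon with annotated CpG sites.

    ``sequence`` carries the C allele at the SNP (so every listed CpG indexes
    a literal "CG").  ``tss_offset`` maps amplicon offsets to TSS-relative
    labels: position i is labelled ``i - tss_offset``.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    tss_offset: int | None = None
    cpg_labels: tuple[str, ...] = ()
    snp: AmpliconSNP | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise InputError("amplicon sequence must be over A/C/G/T")
        object.__setattr__(self, "sequence", seq)
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise InputError("CpG positions must be strictly increasing")
        for pos in self.cpg_positions:
            if not (0 <= pos < len(seq) - 1) or seq[pos : pos + 2] != "CG":
                raise InputError(f"position {pos} does not index a CG dinucleotide")
        if self.snp is not None and self.snp.offset not in self.cpg_positions:
            raise InputError("SNP offset must be one of the CpG positions")
        if not self.cpg_labels:
            if self.tss_offset is not None:
                labels = tuple(
                    f"{p - self.tss_offset:+d}".replace("+", "")
                    if p >= self.tss_offset
                    else str(p - self.tss_offset)
                    for p in self.cpg_positions
                )
            else:
                labels = tuple(str(p) for p in self.cpg_positions)
            object.__setattr__(self, "cpg_labels", labels)
        if len(self.cpg_labels) != len(self.cpg_positions):
            raise InputError("one label per CpG position required")

    @property
    def non_cpg_c_positions(self) -> np.ndarray:
        """Offsets of cytosines outside any annotated CpG (QC sites)."""
        arr = np.frombuffer(self.sequence.encode(), dtype="S1")
        c_pos = np.flatnonzero(arr == b"C")
        return c_pos[~np.isin(c_pos, self.cpg_positions)]

    def allele_sequence(self, allele: str) -> str:
        """Amplicon sequence for one allele ('C' or 'A' at the SNP)."""
        if self.snp is None or allele == "C":
            return self.sequence
        seq = list(self.sequence)
        seq[self.snp.offset] = allele
        return "".join(seq)


def bisulfite_convert_reference(sequence: str) -> str:
    """Fully convert a sequence in silico: every C becomes T."""
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise InputError("sequence must be over A/C/G/T")
    return seq.replace("C", "T")


# ---------------------------------------------------------------------------
# alignment

@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


class MethCall(enum.Enum):
    METHYLATED = "M"
    UNMETHYLATED = "U"
    MISSING = "."


@dataclass
class CloneAlignment:
    """A global alignment of one clone read to the reference amplicon.

    ``ref_to_read`` holds, for every amplicon offset, the read offset aligned
    to it, or -1 where the amplicon base is aligned to a gap.  ``read`` is the
    read in the orientation that was aligned (reverse-complemented when the
    reverse orientation scored higher).
    """

    clone_id: str
    read: str
    ref_to_read: np.ndarray
    score: float
    orientation: str = "forward"
    conversion_efficiency: float | None = None
    allele: str = "unassigned"

    def read_base_at(self, ref_offset: int) -> str | None:
        j = int(self.ref_to_read[ref_offset])
        return None if j < 0 else self.read[j]


def _substitution_scores(
    ref: str, read: str, snp_offset: int | None, scoring: AlignmentScoring
) -> np.ndarray:
    """Position-specific substitution score matrix S[i, j].

    Bisulfite asymmetry: reference C vs read T scores as a match (the read
    derives from converted DNA); reference T vs read C stays a mismatch.  At
    the SNP offset, read A, C or T all score as a match — A is the alternate
    allele, C the methylated and T the converted-unmethylated reference
    allele — so neither allele is penalised.
    """
    r = np.frombuffer(ref.encode(), dtype="S1")[:, None]
    q = np.frombuffer(read.encode(), dtype="S1")[None, :]
    S = np.where(r == q, scoring.match, scoring.mismatch)
    S[(r == b"C") & (q == b"T")] = scoring.match
    if snp_offset is not None:
        S[snp_offset, np.isin(q[0], (b"A", b"C", b"T"))] = scoring.match
    return S


def _nw_dp(S: np.ndarray, gap: float) -> np.ndarray:
    """Needleman–Wunsch score matrix with linear gaps, vectorised per row.

    The within-row (left-gap) recursion max_{k<=j}(M_k + gap*(j-k)) is solved
    as gap*j + cummax(M_k - gap*k), which keeps each row a single numpy pass.
    """
    n, m = S.shape
    H = np.empty((n + 1, m + 1))
    jj = gap * np.arange(m + 1)
    H[0] = jj
    V = np.empty(m + 1)
    for i in range(1, n + 1):
        prev = H[i - 1]
        V[0] = gap * i
        np.maximum(prev[:-1] + S[i - 1], prev[1:] + gap, out=V[1:])
        H[i] = jj + np.maximum.accumulate(V - jj)
    return H


def _traceback(
    H: np.ndarray, S: np.ndarray, gap: float, tol: float = 1e-9
) -> np.ndarray:
    """Recover one optimal path; fixed tie-breaks for bit-reproducibility.

    Preference at ties: diagonal (substitution, i.e. mismatch over gap), then
    gap in the read (consume reference), then gap in the reference — which
    places tied gaps at the earliest opening encountered walking backwards.
    """
    n, m = S.shape
    ref_to_read = np.full(n, -1, dtype=np.int64)
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and abs(H[i - 1, j - 1] + S[i - 1, j - 1] - h) <= tol:
            i, j = i - 1, j - 1
            ref_to_read[i] = j
        elif i > 0 and abs(H[i - 1, j] + gap - h) <= tol:
            i -= 1
        else:
            j -= 1
    return ref_to_read


def align_clone_to_reference(
    read: str,
    amplicon: ReferenceAmplicon,
    scoring: AlignmentScoring = AlignmentScoring(),
    clone_id: str = "",
    try_reverse: bool = True,
) -> CloneAlignment:
    """Globally align a clone read to the amplicon, bisulfite-aware.

    Both the read and its reverse complement are aligned and the better
    orientation kept (forward wins ties), since cloned amplicons are
    sequenced in either direction.
    """
    read = read.upper()
    if not read:
        raise InputError("empty read")
    snp_offset = amplicon.snp.offset if amplicon.snp else None
    candidates = [("forward", read)]
    if try_reverse:
        candidates.append(("reverse", str(Seq(read).reverse_complement())))
    best = None
    for orientation, oriented in candidates:
        S = _substitution_scores(amplicon.sequence, oriented, snp_offset, scoring)
        H = _nw_dp(S, scoring.gap)
        score = float(H[-1, -1])
        if best is None or score > best[0]:
            best = (score, orientation, oriented, S, H)
    score, orientation, oriented, S, H = best
    ref_to_read = _traceback(H, S, scoring.gap)
    return CloneAlignment(
        clone_id=clone_id,
        read=oriented,
        ref_to_read=ref_to_read,
        score=score,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# per-clone calls


def conversion_efficiency(
    alignment: CloneAlignment, amplicon: ReferenceAmplicon
) -> float:
    """Fraction of covered non-CpG reference cytosines read as T.

    Unmethylated non-CpG cytosines should all convert; a low value flags an
    incompletely converted clone.  Gaps and bases other than C/T at these
    positions are excluded from both numerator and denominator.
    """
    n_t = n_c = 0
    for pos in amplicon.non_cpg_c_positions:
        base = alignment.read_base_at(int(pos))
        if base == "T":
            n_t += 1
        elif base == "C":
            n_c += 1
    if n_t + n_c == 0:
        raise UndefinedEfficiencyError(
            f"clone {alignment.clone_id!r} covers no non-CpG cytosine"
        )
    return n_t / (n_t + n_c)


def assign_allele(alignment: CloneAlignment, amplicon: ReferenceAmplicon) -> str:
    """Call the clone's allele from the read base at the SNP offset.

    A means the A allele; C (methylated) or T (converted unmethylated C)
    means the C allele; G or a gap is uninterpretable -> "unassigned".
    """
    if amplicon.snp is None:
        raise InputError("amplicon has no SNP")
    base = alignment.read_base_at(amplicon.snp.offset)
    if base == "A":
        return "A"
    if base in ("C", "T"):
        return "C"
    return "unassigned"


def call_clone_methylation(
    alignment: CloneAlignment, amplicon: ReferenceAmplicon
) -> dict[str, MethCall]:
    """One methylation call per CpG label for a single clone.

    A CpG cytosine read as C is methylated, as T unmethylated; a gap or any
    other base is missing.  The SNP-CpG exists only on the C allele, so it is
    called only for clones assigned to that allele and missing otherwise.
    """
    allele = (
        assign_allele(alignment, amplicon) if amplicon.snp is not None else "C"
    )
    calls: dict[str, MethCall] = {}
    for pos, label in zip(amplicon.cpg_positions, amplicon.cpg_labels):
        if amplicon.snp is not None and pos == amplicon.snp.offset and allele != "C":
            calls[label] = MethCall.MISSING
            continue
        base = alignment.read_base_at(pos)
        if base == "C":
            calls[label] = MethCall.METHYLATED
        elif base == "T":
            calls[label] = MethCall.UNMETHYLATED
        else:
            calls[label] = MethCall.MISSING
    return calls


# ---------------------------------------------------------------------------
# matrix and profiles


@dataclass
class MethylationMatrix:
    """Clones × CpG-site call matrix with per-clone QC.

    ``calls`` holds "M"/"U"/"." strings (rows: clone ids, columns: CpG
    labels); ``qc`` has one row per clone with columns ``conversion``,
    ``allele``, ``score``, ``orientation``.
    """

    calls: pd.DataFrame
    qc: pd.DataFrame

    def passing(self, min_conversion: float = DEFAULT_MIN_CONVERSION) -> pd.Index:
        ok = self.qc["conversion"] >= min_conversion
        return self.qc.index[ok.fillna(False)]


@dataclass
class MethylationProfile:
    """Per-CpG methylated fraction aggregated over passing clones."""

    per_cpg: pd.DataFrame  # columns: methylated, informative, fraction
    n_clones: int

    @property
    def overall_mean(self) -> float:
        """Unweighted mean of per-CpG fractions (each site counts once)."""
        return float(self.per_cpg["fraction"].mean())


@dataclass
class AllelicProfile:
    """Per-allele methylation profiles and their C/A overall-mean ratio."""

    c_allele: MethylationProfile
    a_allele: MethylationProfile
    snp_cpg_fraction: float | None
    ratio: float  # NaN when the A-allele mean is 0

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


def build_methylation_matrix(
    reads: Iterable[tuple[str, str]] | Mapping[str, str],
    amplicon: ReferenceAmplicon,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> MethylationMatrix:
    """Align every clone read and assemble the call matrix + QC table.

    ``reads`` is an iterable of (clone_id, sequence) pairs or a mapping.
    Output row order follows a lexicographic sort of clone ids, so the matrix
    is invariant to input order.
    """
    if isinstance(reads, Mapping):
        reads = list(reads.items())
    rows, qc_rows, ids = [], [], []
    for clone_id, read in sorted(reads):
        aln = align_clone_to_reference(read, amplicon, scoring, clone_id=clone_id)
        try:
            conv = conversion_efficiency(aln, amplicon)
        except UndefinedEfficiencyError:
            conv = np.nan
        allele = assign_allele(aln, amplicon) if amplicon.snp else "C"
        aln.conversion_efficiency = conv
        aln.allele = allele
        calls = call_clone_methylation(aln, amplicon)
        rows.append({k: v.value for k, v in calls.items()})
        qc_rows.append(
            {"conversion": conv, "allele": allele, "score": aln.score,
             "orientation": aln.orientation}
        )
        ids.append(clone_id)
    calls_df = pd.DataFrame(rows, index=ids, columns=list(amplicon.cpg_labels))
    qc_df = pd.DataFrame(qc_rows, index=ids)
    return MethylationMatrix(calls=calls_df, qc=qc_df)


def _profile_from_calls(
    calls: pd.DataFrame, min_informative: int
) -> MethylationProfile:
    meth = (calls == "M").sum(axis=0)
    unmeth = (calls == "U").sum(axis=0)
    informative = meth + unmeth
    keep = informative >= min_informative
    per_cpg = pd.DataFrame(
        {
            "methylated": meth[keep],
            "informative": informative[keep],
            "fraction": (meth[keep] / informative[keep]).astype(float),
        }
    )
    return MethylationProfile(per_cpg=per_cpg, n_clones=len(calls))


def aggregate_profile(
    matrix: MethylationMatrix,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> MethylationProfile:
    """Aggregate passing clones into a per-CpG methylation profile.

    Clones under the conversion threshold are dropped entirely; CpGs with
    fewer informative clones than ``min_informative`` are absent from the
    output (not reported as 0).
    """
    passing = matrix.passing(min_conversion)
    if len(passing) == 0:
        raise EmptyProfileError("no clone passed conversion-efficiency QC")
    return _profile_from_calls(matrix.calls.loc[passing], min_informative)


def allelic_methylation_ratio(
    matrix: MethylationMatrix,
    amplicon: ReferenceAmplicon,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> AllelicProfile:
    """Allele-resolved profiles and the C/A methylation ratio.

    The SNP-CpG itself is excluded from both allelic means (it exists only on
    the C allele); its C-allele fraction is reported separately.  The ratio
    is the C-allele overall mean over the A-allele overall mean, NaN when the
    A-allele mean is zero.
    """
    if amplicon.snp is None:
        raise InputError("amplicon has no SNP: allelic analysis undefined")
    snp_label = amplicon.cpg_labels[amplicon.cpg_positions.index(amplicon.snp.offset)]
    passing = matrix.passing(min_conversion)
    if len(passing) == 0:
        raise EmptyProfileError("no clone passed conversion-efficiency QC")
    qc = matrix.qc.loc[passing]
    shared = [c for c in matrix.calls.columns if c != snp_label]
    profiles: dict[str, MethylationProfile] = {}
    for allele in ("C", "A"):
        clone_ids = qc.index[qc["allele"] == allele]
        if len(clone_ids) < min_informative:
            raise AlleleMissingError(
                allele,
                f"allele {allele!r} has {len(clone_ids)} passing clones "
                f"(need >= {min_informative})",
            )
        profiles[allele] = _profile_from_calls(
            matrix.calls.loc[clone_ids, shared], min_informative
        )
    c_ids = qc.index[qc["allele"] == "C"]
    snp_calls = matrix.calls.loc[c_ids, snp_label]
    n_m, n_u = (snp_calls == "M").sum(), (snp_calls == "U").sum()
    snp_fraction = n_m / (n_m + n_u) if (n_m + n_u) > 0 else None
    a_mean = profiles["A"].overall_mean
    ratio = profiles["C"].overall_mean / a_mean if a_mean > 0 else float("nan")
    return AllelicProfile(
        c_allele=profiles["C"],
        a_allele=profiles["A"],
        snp_cpg_fraction=snp_fraction,
        ratio=ratio,
    )


def format_lollipop(matrix: MethylationMatrix) -> str:
    """Plain-text clones × CpG lollipop matrix (● methylated, ○ not, · missing)."""
    symbols = {"M": "●", "U": "○", ".": "·"}
    width = max(len(i) for i in matrix.calls.index) if len(matrix.calls) else 5
    header = " " * (width + 1) + " ".join(matrix.calls.columns)
    lines = [header]
    for clone_id, row in matrix.calls.iterrows():
        cells = " ".join(
            symbols[v].center(len(c)) for c, v in zip(matrix.calls.columns, row)
        )
        lines.append(f"{clone_id:<{width}} {cells}")
    return "\n".join(lines)
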