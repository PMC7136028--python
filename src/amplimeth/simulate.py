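"""Synthetic data generators for the methylation–inducibility pipeline.

Four generators cover the data structures the analysis consumes:

* promoter sequences with a prescribed observed/expected CpG ratio;
* reversible promoter-methylation trajectories under cytokine stimulation
  and washout, modelled as two piecewise first-order exponential
  relaxations (demethylation towards an induced floor while stimulated,
  re-methylation back towards baseline after withdrawal);
* clone-level bisulfite reads from a diploid locus carrying a
  CpG-destroying C/A SNP, with configurable conversion efficiency and
  sequencing error, plus ground-truth labels;
* gene cohorts pairing promoter CpG density with resting/induced expression
  counts and promoter methylation, where CpG-poor promoters of inducible
  genes are coupled to larger expression and methylation changes.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import AmpliconSNP, ReferenceAmplicon
from .cpg import CGI_RATIO_THRESHOLD, cpg_obs_exp_ratio
from .errors import InfeasibleSequenceError, InputError

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


# ---------------------------------------------------------------------------
# reversible methylation dynamics


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the reversible promoter-methylation model.

    During stimulation methylation relaxes from the baseline ``m0`` towards
    the induced floor ``m_ind`` at rate ``k_down`` (per hour); after
    withdrawal at ``t_stim_end`` it relaxes back towards ``m0`` at ``k_up``.
    Defaults are illustrative (no measured rates exist for this system) and
    mirror a 48 h stimulation / 36 h washout design.
    """

    m0: float = 0.8
    m_ind: float = 0.2
    k_down: float = 0.2
    k_up: float = 0.1
    t_stim_end: float = 48.0

    def __post_init__(self):
        if not (0 <= self.m_ind <= self.m0 <= 1):
            raise InputError("need 0 <= m_ind <= m0 <= 1")
        for rate in (self.k_down, self.k_up):
            if not np.isfinite(rate) or rate < 0:
                raise InputError("rates must be finite and non-negative")
        if self.t_stim_end <= 0:
            raise InputError("t_stim_end must be positive")


def simulate_methylation_trajectory(
    params: DynamicsParams, timepoints: Sequence[float]
) -> np.ndarray:
    """Mean per-CpG methylation probability at each timepoint (closed form).

    m(t) = m_ind + (m0 - m_ind) e^{-k_down t}            for t <= t_stim_end
    m(t) = m0 - (m0 - m(t_e)) e^{-k_up (t - t_e)}        for t >  t_stim_end
    """
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise InputError("timepoints must be sorted and non-negative")
    span = params.m0 - params.m_ind
    m = params.m_ind + span * np.exp(-params.k_down * t)
    after = t > params.t_stim_end
    if np.any(after):
        m_end = params.m_ind + span * np.exp(-params.k_down * params.t_stim_end)
        m[after] = params.m0 - (params.m0 - m_end) * np.exp(
            -params.k_up * (t[after] - params.t_stim_end)
        )
    return m


# ---------------------------------------------------------------------------
# promoter sequence generator


def _count_cg(seq: np.ndarray) -> int:
    return int(np.count_nonzero((seq[:-1] == b"C") & (seq[1:] == b"G")))


def simulate_promoter_sequence(
    length: int,
    gc_content: float,
    target_ratio: float,
    seed: int,
    max_retries: int = 20,
) -> str:
    """Generate a random sequence with a prescribed CpG obs/exp ratio.

    Base composition is fixed from ``gc_content``; the number of CG
    dinucleotides is set to round(target_ratio * n_C * n_G / length) and a
    stochastic swap-repair walk adjusts a shuffled sequence to that count
    exactly (swaps preserve composition, so the achieved ratio is exact up
    to the rounding of the CG count).  Raises
    :class:`InfeasibleSequenceError` when the combination cannot be
    realised within bounded retries.
    """
    if length < 200:
        raise InputError("length must be >= 200")
    if not (0 < gc_content < 1):
        raise InputError("gc_content must be in (0, 1)")
    if target_ratio < 0:
        raise InputError("target_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    n_c = int(round(gc_content * length / 2))
    n_g = int(round(gc_content * length)) - n_c
    n_a = (length - n_c - n_g + 1) // 2
    n_t = length - n_c - n_g - n_a
    k = int(round(target_ratio * n_c * n_g / length))
    if k > min(n_c, n_g) or (target_ratio > 0 and min(n_c, n_g) == 0):
        raise InfeasibleSequenceError(
            f"cannot place {k} CpGs with n_C={n_c}, n_G={n_g}"
        )
    if k < min(n_c, n_g) and n_a + n_t == 0:
        raise InfeasibleSequenceError("no A/T bases available to break CpGs")
    base_pool = np.repeat(_BASES, [n_a, n_c, n_g, n_t])
    for _ in range(max_retries):
        seq = base_pool.copy()
        rng.shuffle(seq)
        if _repair_cg_count(seq, k, rng):
            achieved = cpg_obs_exp_ratio(seq.tobytes().decode()).ratio
            if length < 500 or abs(achieved - target_ratio) <= 0.05:
                return seq.tobytes().decode()
    raise InfeasibleSequenceError(
        f"failed to reach target_ratio={target_ratio} "
        f"(length={length}, gc={gc_content}) after {max_retries} retries"
    )


def _repair_cg_count(seq: np.ndarray, k: int, rng: np.random.Generator) -> bool:
    """Swap bases in place until the sequence has exactly k CG dinucleotides."""
    for _ in range(10 * len(seq) + 100):
        cg_starts = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        if len(cg_starts) == k:
            return True
        if len(cg_starts) > k:
            # break a random CG: swap its G with a random A/T elsewhere
            at_pos = np.flatnonzero((seq == b"A") | (seq == b"T"))
            if len(at_pos) == 0:
                return False
            p = int(rng.choice(cg_starts)) + 1
            q = int(rng.choice(at_pos))
        else:
            # form a CG: put a G right after a C that lacks one
            c_pos = np.flatnonzero(seq[:-1] == b"C")
            c_pos = c_pos[seq[c_pos + 1] != b"G"]
            g_pos = np.flatnonzero(seq == b"G")
            if len(c_pos) == 0 or len(g_pos) == 0:
                return False
            p = int(rng.choice(c_pos)) + 1
            q = int(rng.choice(g_pos))
        seq[p], seq[q] = seq[q], seq[p]
    return False


def simulate_amplicon(
    length: int,
    cpg_offsets: Sequence[int],
    gc_content: float,
    seed: int,
    name: str = "amplicon",
    snp_offset: int | None = None,
    tss_offset: int | None = None,
    snp_label: str = "",
    max_retries: int = 20,
) -> ReferenceAmplicon:
    """Generate a reference amplicon with CpGs at prescribed offsets only.

    CG dinucleotides are pinned at ``cpg_offsets`` (no two adjacent) and the
    rest of the sequence is a composition-constrained shuffle repaired to
    contain no further CG.  The achieved obs/exp ratio is therefore
    len(cpg_offsets) * length / (n_C * n_G) exactly.  ``snp_offset`` marks
    one of the CpGs as a C/A SNP site.
    """
    offsets = sorted(set(int(o) for o in cpg_offsets))
    if not offsets:
        raise InputError("need at least one CpG offset")
    if offsets[0] < 0 or offsets[-1] + 1 >= length:
        raise InputError("CpG offsets out of bounds")
    if any(b - a < 2 for a, b in zip(offsets, offsets[1:])):
        raise InputError("CpG offsets must be at least 2 apart")
    if snp_offset is not None and snp_offset not in offsets:
        raise InputError("snp_offset must be one of the CpG offsets")
    k = len(offsets)
    n_c = int(round(gc_content * length / 2))
    n_g = int(round(gc_content * length)) - n_c
    if n_c < k or n_g < k:
        raise InfeasibleSequenceError("gc_content too low for the requested CpGs")
    n_free = length - 2 * k
    free_c, free_g = n_c - k, n_g - k
    n_a = (n_free - free_c - free_g + 1) // 2
    n_t = n_free - free_c - free_g - n_a
    if n_a < 0 or n_t < 0:
        raise InfeasibleSequenceError("gc_content too high for the window")

    rng = np.random.default_rng(seed)
    block = np.zeros(length, dtype=bool)
    for o in offsets:
        block[o] = block[o + 1] = True
    free_idx = np.flatnonzero(~block)
    pool = np.repeat(_BASES, [n_a, free_c, free_g, n_t])
    for _ in range(max_retries):
        seq = np.empty(length, dtype="S1")
        for o in offsets:
            seq[o], seq[o + 1] = b"C", b"G"
        filler = pool.copy()
        rng.shuffle(filler)
        seq[free_idx] = filler
        if _repair_stray_cgs(seq, set(offsets), rng):
            return ReferenceAmplicon(
                name=name,
                sequence=seq.tobytes().decode(),
                cpg_positions=tuple(offsets),
                tss_offset=tss_offset,
                snp=(
                    AmpliconSNP(offset=snp_offset, label=snp_label)
                    if snp_offset is not None
                    else None
                ),
            )
    raise InfeasibleSequenceError("could not remove stray CpGs")


def _repair_stray_cgs(
    seq: np.ndarray, keep: set[int], rng: np.random.Generator
) -> bool:
    """Swap bases until the only CG dinucleotides start at ``keep`` offsets."""
    for _ in range(10 * len(seq) + 100):
        starts = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        stray = [s for s in starts if s not in keep]
        if not stray:
            return True
        at_pos = np.flatnonzero((seq == b"A") | (seq == b"T"))
        # avoid landing the displaced G right after a C (would form a new CG)
        at_pos = at_pos[(at_pos == 0) | (seq[at_pos - 1] != b"C")]
        if len(at_pos) == 0:
            return False
        p = int(rng.choice(stray)) + 1
        q = int(rng.choice(at_pos))
        seq[p], seq[q] = seq[q], seq[p]
    return False


# ---------------------------------------------------------------------------
# bisulfite clone simulator


@dataclass(frozen=True)
class CloneSimConfig:
    """Sampling model for clone-level bisulfite reads.

    ``conversion_efficiency`` is the probability an unmethylated C reads T;
    ``error_rate`` is a uniform per-base substitution probability applied
    after conversion; ``allele_fractions`` gives the diploid sampling mix
    (allele-balanced by default).
    """

    n_clones: int = 50
    conversion_efficiency: float = 0.99
    error_rate: float = 0.001
    allele_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.5, "A": 0.5}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1:
            raise InputError("n_clones must be >= 1")
        for p in (self.conversion_efficiency, self.error_rate):
            if not (0 <= p <= 1):
                raise InputError("probabilities must be in [0, 1]")
        total = sum(self.allele_fractions.values())
        if abs(total - 1.0) > 1e-9 or any(
            p < 0 for p in self.allele_fractions.values()
        ):
            raise InputError("allele fractions must be non-negative and sum to 1")


@dataclass(frozen=True)
class SimulatedClone:
    """One simulated clone read with its ground truth."""

    clone_id: str
    read: str
    allele: str
    meth_truth: tuple  # per amplicon CpG: True/False, or None if absent


def simulate_bisulfite_clones(
    amplicon: ReferenceAmplicon,
    per_cpg_meth_probs: Mapping[str, Sequence[float]] | Sequence[float],
    config: CloneSimConfig = CloneSimConfig(),
) -> list[SimulatedClone]:
    """Simulate bisulfite-converted clone reads from a (possibly diploid) locus.

    ``per_cpg_meth_probs`` maps allele label -> one methylation probability
    per amplicon CpG (a bare sequence means a single 'C' allele).  For the A
    allele the SNP-CpG entry is ignored: that CpG does not exist there.  Per
    clone: the allele is drawn from ``allele_fractions``, each CpG's
    methylation state from Bernoulli(p); unmethylated Cs (CpG and non-CpG)
    read T with probability ``conversion_efficiency``, methylated CpG Cs read
    C; uniform substitution errors are applied last.
    """
    fractions = dict(config.allele_fractions)
    if not isinstance(per_cpg_meth_probs, Mapping):
        # bare probability vector: single-allele (haploid) locus
        per_cpg_meth_probs = {"C": per_cpg_meth_probs}
        fractions = {"C": 1.0}
    n_cpg = len(amplicon.cpg_positions)
    probs = {}
    for allele, vec in per_cpg_meth_probs.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (n_cpg,):
            raise InputError(
                f"allele {allele!r}: expected {n_cpg} probabilities, got {arr.shape}"
            )
        if np.any((arr < 0) | (arr > 1)):
            raise InputError("methylation probabilities must be in [0, 1]")
        probs[allele] = arr
    unknown = set(fractions) - set(probs)
    if unknown:
        raise InputError(f"allele fractions name alleles without probabilities: {unknown}")

    rng = np.random.default_rng(config.seed)
    alleles = list(fractions)
    weights = np.array([fractions[a] for a in alleles])
    cpg_pos = np.array(amplicon.cpg_positions, dtype=int)
    snp_off = amplicon.snp.offset if amplicon.snp else None
    clones = []
    n_digits = len(str(config.n_clones))
    for idx in range(config.n_clones):
        allele = alleles[int(rng.choice(len(alleles), p=weights))]
        seq = np.frombuffer(
            amplicon.allele_sequence(allele).encode(), dtype="S1"
        ).copy()
        meth = rng.random(n_cpg) < probs[allele]
        truth = []
        for i, pos in enumerate(cpg_pos):
            if snp_off is not None and pos == snp_off and allele != "C":
                truth.append(None)
                meth[i] = False  # site absent: its C (now A) cannot stay C
            else:
                truth.append(bool(meth[i]))
        read = seq.copy()
        is_c = read == b"C"
        protected = np.zeros(len(read), dtype=bool)
        protected[cpg_pos[np.asarray(meth, dtype=bool)]] = True
        convertible = is_c & ~protected
        converts = convertible & (rng.random(len(read)) < config.conversion_efficiency)
        read[converts] = b"T"
        if config.error_rate > 0:
            hit = rng.random(len(read)) < config.error_rate
            for p in np.flatnonzero(hit):
                others = _BASES[_BASES != read[p]]
                read[p] = others[int(rng.integers(3))]
        clones.append(
            SimulatedClone(
                clone_id=f"clone_{idx:0{n_digits}d}",
                read=read.tobytes().decode(),
                allele=allele,
                meth_truth=tuple(truth),
            )
        )
    return clones


def write_clones_fasta(clones: Iterable[SimulatedClone], path: str | Path) -> None:
    """Write clone reads as FASTA; truth labels go in the description field."""
    records = []
    for clone in clones:
        truth = "".join(
            "." if m is None else ("1" if m else "0") for m in clone.meth_truth
        )
        records.append(
            SeqRecord(
                Seq(clone.read),
                id=clone.clone_id,
                description=f"allele={clone.allele}\tmeth={truth}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_clones_fasta(path: str | Path) -> list[SimulatedClone]:
    """Read back clone reads written by :func:`write_clones_fasta`."""
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1)
            for kv in rec.description.split()
            if "=" in kv
        )
        truth = tuple(
            None if ch == "." else ch == "1" for ch in fields.get("meth", "")
        )
        clones.append(
            SimulatedClone(
                clone_id=rec.id,
                read=str(rec.seq),
                allele=fields.get("allele", "C"),
                meth_truth=truth,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# gene cohort simulator


@dataclass(frozen=True)
class CohortConfig:
    """Generative model for a resting/induced gene cohort.

    Promoter CpG ratios come from a two-mode mixture (CpG-poor ~0.2, CGI
    ~0.8) straddling the 0.6 island threshold.  A gene's CpG-poverty score
    s = max(0, 1 - ratio/0.6) enters twice, mirroring the emulated biology
    in which CpG-poor promoters are both more likely to respond and respond
    more strongly: a gene is responsive with probability
    ``inducible_base + inducible_poverty_slope * s`` (Bernoulli flag B), and
    responsive genes change expression by ``coupling_beta * s`` in log2
    units and promoter methylation by ``meth_coupling * s``.  The response
    direction is up with probability ``induced_up_fraction`` and down
    otherwise — acute inflammation both induces and represses genes — and
    the methylation change opposes the expression change (induced genes
    demethylate, repressed genes gain methylation).  CGI promoters start
    near zero methylation and barely change.  Counts are negative-binomial
    around CPM-scaled means at mean library size ``depth``.
    """

    n_genes: int = 4000
    coupling_beta: float = 2.0
    meth_coupling: float = 0.4
    baseline_log2fc_sd: float = 0.3
    nb_dispersion: float = 0.05
    depth: float = 1e6
    n_replicates: int = 3
    inducible_base: float = 0.1
    inducible_poverty_slope: float = 0.5
    induced_up_fraction: float = 0.5
    cpg_poor_weight: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 8:
            raise InputError("n_genes must be >= 8 (quartiles must be nonempty)")
        for name in ("coupling_beta", "meth_coupling", "baseline_log2fc_sd",
                     "nb_dispersion", "depth"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        for name in ("inducible_base", "inducible_poverty_slope",
                     "induced_up_fraction", "cpg_poor_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise InputError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene: str
    cpg_ratio: float
    log2fc: float
    meth_resting: float
    meth_induced: float
    cgi: bool


@dataclass
class Cohort:
    """A simulated resting/induced cohort.

    ``genes``: per-gene truth table (cpg_ratio, cgi, inducible, true_log2fc,
    meth_resting, meth_induced).  ``counts``: genes × samples read counts.
    ``sample_info``: sample -> condition map.
    """

    genes: pd.DataFrame
    counts: pd.DataFrame
    sample_info: pd.DataFrame
    config: CohortConfig

    def truth_records(self) -> list[GeneTruth]:
        return [
            GeneTruth(
                gene=g,
                cpg_ratio=row["cpg_ratio"],
                log2fc=row["true_log2fc"],
                meth_resting=row["meth_resting"],
                meth_induced=row["meth_induced"],
                cgi=bool(row["cgi"]),
            )
            for g, row in self.genes.iterrows()
        ]


def simulate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Simulate a paired resting/induced cohort with known coupling."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    poor = rng.random(n) < config.cpg_poor_weight
    ratio = np.where(poor, rng.beta(4, 16, n), rng.beta(16, 4, n))
    cgi = ratio > CGI_RATIO_THRESHOLD
    poverty = np.maximum(0.0, 1.0 - ratio / CGI_RATIO_THRESHOLD)
    p_responsive = np.clip(
        config.inducible_base + config.inducible_poverty_slope * poverty, 0, 1
    )
    inducible = rng.random(n) < p_responsive
    sign = np.where(rng.random(n) < config.induced_up_fraction, 1.0, -1.0)

    log2fc = (
        sign * config.coupling_beta * poverty * inducible
        + rng.normal(0.0, config.baseline_log2fc_sd, n)
    )

    meth_resting = np.where(
        cgi, rng.uniform(0.0, 0.1, n), rng.uniform(0.55, 0.95, n)
    )
    # methylation moves opposite to expression: induction demethylates,
    # repression re-methylates
    meth_shift = -sign * config.meth_coupling * poverty * inducible
    meth_noise = np.where(cgi, rng.normal(0, 0.01, n), rng.normal(0, 0.02, n))
    meth_induced = np.clip(meth_resting + meth_shift + meth_noise, 0.0, 1.0)

    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    prop_rest = abundance / abundance.sum()
    induced_abundance = abundance * np.exp2(log2fc)
    prop_ind = induced_abundance / induced_abundance.sum()

    counts = {}
    sample_rows = []
    for cond, prop in (("resting", prop_rest), ("induced", prop_ind)):
        mean = config.depth * prop
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_{rep}"
            if config.nb_dispersion > 0:
                size = 1.0 / config.nb_dispersion
                counts[sample] = rng.negative_binomial(
                    size, size / (size + mean)
                )
            else:
                counts[sample] = rng.poisson(mean)
            sample_rows.append({"sample": sample, "condition": cond})

    genes_df = pd.DataFrame(
        {
            "cpg_ratio": ratio,
            "cgi": cgi,
            "inducible": inducible,
            "true_log2fc": log2fc,
            "meth_resting": meth_resting,
            "meth_induced": meth_induced,
        },
        index=pd.Index(genes, name="gene"),
    )
    counts_df = pd.DataFrame(counts, index=genes_df.index)
    sample_df = pd.DataFrame(sample_rows).set_index("sample")
    return Cohort(genes=genes_df, counts=counts_df, sample_info=sample_df,
                  config=config)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write cohort tables as TSV with a JSON sidecar of the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.genes.to_csv(outdir / "genes.tsv", sep="\t")
    cohort.counts.to_csv(outdir / "counts.tsv", sep="\t")
    cohort.sample_info.to_csv(outdir / "samples.tsv", sep="\t")
    cfg = asdict(cohort.config)
    (outdir / "cohort_config.json").write_text(json.dumps(cfg, indent=2) + "\n")
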