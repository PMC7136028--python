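"""File-format plumbing: FASTA, BED6, bedGraph-like TSV, matrices, provenance.

All formats are plain text.  Readers return the package's in-memory
containers; writers are deterministic so repeated runs with the same seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from . import __version__
from .bisulfite import AmpliconSNP, MethylationMatrix, MethylationProfile, ReferenceAmplicon
from .cpg import PromoterWindow
from .errors import InputError
from .induction import CountMatrix


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed6(path: str | Path, upstream: int, downstream: int) -> list[PromoterWindow]:
    """Read TSS positions from BED6 into promoter windows.

    The BED interval's strand-aware 5' end is taken as the TSS (start for +,
    end-1 for −); ``name`` is the gene id.  Coordinates are 0-based
    half-open, as in BED.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    windows = []
    for row in bed.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        windows.append(
            PromoterWindow(
                gene=str(row.name), chrom=str(row.chrom), tss=tss,
                strand=str(row.strand), upstream=upstream, downstream=downstream,
            )
        )
    return windows


def read_bedgraph_methylation(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph-like per-CpG table: chrom, start, end, methylated, total."""
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "methylated", "total"],
    )
    if (table["methylated"] > table["total"]).any():
        raise InputError("methylated count exceeds total coverage")
    return table


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a genes × samples TSV plus its sample -> condition sidecar."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if "condition" not in samples.columns:
        raise InputError("sample sidecar must have a 'condition' column")
    timepoint = samples["timepoint"] if "timepoint" in samples.columns else None
    return CountMatrix(counts=counts, condition=samples["condition"],
                       timepoint=timepoint)


def load_amplicon(fasta_path: str | Path, descriptor_path: str | Path) -> ReferenceAmplicon:
    """Load a reference amplicon from FASTA + JSON descriptor.

    The descriptor carries ``cpg_positions`` (0-based offsets), optional
    ``tss_offset``, ``cpg_labels`` and ``snp`` ({offset, alleles, label}).
    """
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise InputError("amplicon FASTA must contain exactly one record")
    name, sequence = next(iter(seqs.items()))
    meta = json.loads(Path(descriptor_path).read_text())
    snp = None
    if meta.get("snp"):
        snp = AmpliconSNP(
            offset=int(meta["snp"]["offset"]),
            alleles=tuple(meta["snp"].get("alleles", ("C", "A"))),
            label=meta["snp"].get("label", ""),
        )
    return ReferenceAmplicon(
        name=meta.get("name", name),
        sequence=sequence,
        cpg_positions=tuple(meta["cpg_positions"]),
        tss_offset=meta.get("tss_offset"),
        cpg_labels=tuple(meta.get("cpg_labels", ())),
        snp=snp,
    )


def write_matrix_tsv(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write the clones × CpG call matrix (M/U/.) with QC columns appended."""
    out = matrix.calls.join(matrix.qc)
    out.index.name = "clone"
    out.to_csv(path, sep="\t")


def write_profile_tsv(profile: MethylationProfile, path: str | Path) -> None:
    out = profile.per_cpg.copy()
    out.index.name = "cpg"
    out.to_csv(path, sep="\t")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    outdir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Write a machine-readable provenance record next to a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "amplimeth",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "input_checksums": {str(p): sha256_of(p) for p in inputs},
    }
    path = outdir / "provenance.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    tmp.replace(path)
    return path
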