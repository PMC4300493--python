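"""Input/output, A-site assignment, gene filtering and profile construction.

Coordinates are 0-based codon indices with half-open ranges.  Sequences are
stored as uppercase DNA (U is normalized to T).  A gene's length ``L`` is the
number of *sense* codons: the terminal stop codon, when present in the CDS,
is never part of a footprint profile.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# A-site offset (nt from the read 5' end) by reading-frame phase of the read
# start: phase 0 (first nt of a codon) -> 15, phase 1 (middle) -> 17,
# phase 2 (last) -> 16.
_ASITE_OFFSET_BY_PHASE = {0: 15, 1: 17, 2: 16}
MIN_READ_LENGTH = 28
MAX_READ_LENGTH = 31


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A coding sequence with optional UTRs and Kozak context.

    ``cds`` may or may not include the terminal stop codon; ``n_codons``
    always counts sense codons only.
    """

    gene_id: str
    cds: str
    utr5: str | None = None
    utr3: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", _normalize_seq(self.cds))
        if self.utr5 is not None:
            object.__setattr__(self, "utr5", _normalize_seq(self.utr5))
        if self.utr3 is not None:
            object.__setattr__(self, "utr3", _normalize_seq(self.utr3))
        if len(self.cds) < 6 or len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length must be >= 6 and divisible by 3, "
                f"got {len(self.cds)}"
            )
        if set(self.cds) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: CDS has non-ACGT/U characters")

    @property
    def codons(self) -> list[str]:
        """Sense codons (terminal stop, if any, excluded)."""
        cods = [self.cds[i:i + 3] for i in range(0, len(self.cds), 3)]
        if cods and cods[-1] in STOP_CODONS:
            cods = cods[:-1]
        return cods

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def kozak_context(self) -> str | None:
        """12-nt context spanning -6..+6 around the start (ATG included).

        Requires a 5' UTR of at least 6 nt; returns None otherwise.
        """
        if self.utr5 is None or len(self.utr5) < 6:
            return None
        return self.utr5[-6:] + self.cds[:6]

    def has_aug_start(self) -> bool:
        return self.cds.startswith("ATG")

    def has_internal_stop(self) -> bool:
        cods = [self.cds[i:i + 3] for i in range(0, len(self.cds), 3)]
        return any(c in STOP_CODONS for c in cods[:-1])


@dataclasses.dataclass
class FootprintProfile:
    """Per-gene codon-resolution footprint counts plus mRNA measurements.

    ``counts[k]`` is the observed footprint count at codon ``k`` (the
    observable proxy for ribosome occupancy); ``mrna_counts`` the per-codon
    mRNA fragment counts; ``mrna_abundance`` the gene-level mRNA level.
    """

    gene_id: str
    counts: np.ndarray
    mrna_counts: np.ndarray | None = None
    mrna_abundance: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError(f"{self.gene_id}: counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}: negative footprint counts")
        if self.mrna_counts is not None:
            self.mrna_counts = np.asarray(self.mrna_counts)
            if self.mrna_counts.shape != self.counts.shape:
                raise ValueError(f"{self.gene_id}: mRNA track length mismatch")
            if np.any(self.mrna_counts < 0):
                raise ValueError(f"{self.gene_id}: negative mRNA counts")
        if self.mrna_abundance < 0:
            raise ValueError(f"{self.gene_id}: negative mRNA abundance")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_count(self) -> float:
        """Mean raw footprint count per codon (the fixed initial flow D)."""
        return float(np.mean(self.counts))


@dataclasses.dataclass(frozen=True)
class FilterReport:
    gene_id: str
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be true iff reasons is empty")


class ReadRejected(Exception):
    """A footprint read that cannot be assigned to an active codon."""


def assign_asite(read_start: int, read_length: int, n_codons: int | None = None) -> int:
    """Map a footprint read to the codon index holding its ribosomal A-site.

    ``read_start`` is the 0-based nt position of the read 5' end relative to
    the first nt of the CDS (negative = upstream of the start codon).  If the
    read begins on the first / last / middle nucleotide of a codon, the
    active codon starts at read nucleotide 15 / 16 / 17 respectively.  Only
    read lengths 28-31 are accepted.

    Parameters
    ----------
    read_start : int
        5' end of the read, 0-based nt within the CDS frame.
    read_length : int
        Footprint length in nt; must be in 28..31.
    n_codons : int, optional
        Number of sense codons; if given, A-sites beyond the coding region
        are rejected.

    Returns
    -------
    int
        0-based codon index of the active codon.

    Raises
    ------
    ReadRejected
        If the read length is outside 28-31 or the A-site falls outside the
        coding region.
    """
    if not (MIN_READ_LENGTH <= read_length <= MAX_READ_LENGTH):
        raise ReadRejected(
            f"read length {read_length} outside {MIN_READ_LENGTH}-{MAX_READ_LENGTH}"
        )
    phase = read_start % 3  # python modulo: correct phase also for negative starts
    offset = _ASITE_OFFSET_BY_PHASE[phase]
    asite_nt = read_start + offset
    if asite_nt < 0:
        raise ReadRejected(f"A-site nt {asite_nt} upstream of CDS")
    codon_index = asite_nt // 3
    if n_codons is not None and codon_index >= n_codons:
        raise ReadRejected(f"A-site codon {codon_index} beyond CDS end ({n_codons})")
    return codon_index


def mrna_fragment_maps(read_start: int, cds_len_nt: int) -> bool:
    """Optional read-level rule for raw mRNA fragment positions.

    A fragment maps to a gene if it begins less than 16 nt upstream of the
    start codon and more than 16 nt upstream of the stop codon.  Users who
    supply per-position mRNA counts bypass this entirely.
    """
    return read_start > -16 and read_start < cds_len_nt - 16


def build_profiles(
    asite_calls: Mapping[str, Iterable[int]],
    genes: Iterable[GeneRecord],
    mrna_calls: Mapping[str, Iterable[int]] | None = None,
    mrna_abundance: Mapping[str, float] | None = None,
) -> dict[str, FootprintProfile]:
    """Aggregate A-site codon calls into per-gene count profiles."""
    out: dict[str, FootprintProfile] = {}
    for gene in genes:
        L = gene.n_codons
        counts = np.zeros(L, dtype=np.int64)
        for k in asite_calls.get(gene.gene_id, ()):
            if not (0 <= k < L):
                raise IndexError(
                    f"gene {gene.gene_id}: codon index {k} outside [0, {L})"
                )
            counts[k] += 1
        mcounts = None
        if mrna_calls is not None:
            mcounts = np.zeros(L, dtype=np.int64)
            for k in mrna_calls.get(gene.gene_id, ()):
                if not (0 <= k < L):
                    raise IndexError(
                        f"gene {gene.gene_id}: mRNA codon index {k} outside [0, {L})"
                    )
                mcounts[k] += 1
        ab = float(mrna_abundance.get(gene.gene_id, 0.0)) if mrna_abundance else 0.0
        out[gene.gene_id] = FootprintProfile(gene.gene_id, counts, mcounts, ab)
    return out


def filter_genes(
    genes: Iterable[GeneRecord],
    profiles: Mapping[str, FootprintProfile],
    min_mrna_coverage: float = 0.5,
) -> tuple[dict[str, GeneRecord], list[FilterReport]]:
    """Apply the standard gene filters and report every triggered rule.

    A gene is dropped if it lacks an AUG start codon, contains an internal
    stop codon, has mRNA counts at fewer than 50% of its coding positions,
    or has all-zero footprint counts over the model's restricted region.
    """
    from riboflow.flowmodel import restricted_positions

    kept: dict[str, GeneRecord] = {}
    reports: list[FilterReport] = []
    for gene in genes:
        reasons: list[str] = []
        if not gene.has_aug_start():
            reasons.append("no_aug_start")
        if gene.has_internal_stop():
            reasons.append("internal_stop")
        prof = profiles.get(gene.gene_id)
        if prof is None:
            reasons.append("missing_profile")
        else:
            if prof.mrna_counts is not None:
                cov = float(np.mean(prof.mrna_counts >= 1))
                if cov < min_mrna_coverage:
                    reasons.append("low_mrna_coverage")
            r = restricted_positions(prof.length)
            if len(r) == 0 or not np.any(prof.counts[r.start:r.stop]):
                reasons.append("zero_footprints_in_model_region")
        rep = FilterReport(gene.gene_id, kept=not reasons, reasons=tuple(reasons))
        reports.append(rep)
        if rep.kept:
            kept[gene.gene_id] = gene
    return kept, reports


# ---------------------------------------------------------------------------
# Table and FASTA I/O


def read_cds_fasta(path: str | Path) -> dict[str, GeneRecord]:
    """Read coding sequences from FASTA; duplicate ids are an error."""
    genes: dict[str, GeneRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genes:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id}")
        genes[rec.id] = GeneRecord(rec.id, str(rec.seq))
    return genes


def read_counts_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a TSV of (gene_id, position, count) into dense per-gene arrays.

    Positions are 0-based codon indices; unlisted positions are zero.
    Duplicate (gene, position) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "position", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df[df["position"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative position at data row {bad.index[0]}")
    dup = df.duplicated(subset=["gene_id", "position"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for ({row['gene_id']}, {row['position']})"
        )
    out: dict[str, np.ndarray] = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        L = int(grp["position"].max()) + 1
        arr = np.zeros(L, dtype=np.int64)
        arr[grp["position"].to_numpy(dtype=np.int64)] = grp["count"].to_numpy()
        out[str(gid)] = arr
    return out


def write_counts_table(path: str | Path, counts: Mapping[str, Sequence[int]]) -> None:
    """Write per-gene count arrays as a (gene_id, position, count) TSV.

    Every position is written, including zeros, so the round trip is exact.
    """
    rows = []
    for gid, arr in counts.items():
        for k, v in enumerate(np.asarray(arr)):
            rows.append((gid, k, int(v)))
    pd.DataFrame(rows, columns=["gene_id", "position", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_abundance_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    if df["gene_id"].duplicated().any():
        gid = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {gid}")
    return dict(zip(df["gene_id"], df["abundance"].astype(float)))


def write_abundance_table(path: str | Path, abundance: Mapping[str, float]) -> None:
    pd.DataFrame(
        {"gene_id": list(abundance), "abundance": list(abundance.values())}
    ).to_csv(path, sep="\t", index=False)


def write_fit(outdir: str | Path, fit) -> None:
    """Write a ModelFit as three TSV tables (global dwells, per-gene dwells, flows).

    Values are written at full precision so write->read is an identity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"codon": list(fit.mu_global), "mu": list(fit.mu_global.values())}
    ).to_csv(outdir / "mu_global.tsv", sep="\t", index=False, float_format="%.17g")
    rows = [(g, c, mu) for (g, c), mu in fit.mu_gene.items()]
    pd.DataFrame(rows, columns=["gene_id", "codon", "mu"]).to_csv(
        outdir / "mu_gene.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame({"gene_id": list(fit.J), "J": list(fit.J.values())}).to_csv(
        outdir / "flows.tsv", sep="\t", index=False, float_format="%.17g"
    )


def read_fit(outdir: str | Path):
    """Read tables written by :func:`write_fit` back into a ModelFit."""
    from riboflow.flowmodel import FitConfig, ModelFit

    outdir = Path(outdir)
    mg = pd.read_csv(outdir / "mu_global.tsv", sep="\t",
                     float_precision="round_trip")
    mu_global = dict(zip(mg["codon"], mg["mu"].astype(float)))
    mgene = pd.read_csv(outdir / "mu_gene.tsv", sep="\t", dtype={"gene_id": str},
                        float_precision="round_trip")
    mu_gene = {
        (str(r.gene_id), str(r.codon)): float(r.mu) for r in mgene.itertuples()
    }
    fl = pd.read_csv(outdir / "flows.tsv", sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    J = dict(zip(fl["gene_id"], fl["J"].astype(float)))
    return ModelFit(
        mu_gene=mu_gene, mu_global=mu_global, J=J, weights={},
        objective_trace=[], config=FitConfig(),
    )
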