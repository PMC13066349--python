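"""Readers, writers and configuration for the pipeline's file formats.

All tabular formats are UTF-8, tab-separated, dot-decimal, with one header
line; metadata lines start with ``#`` and are ignored on read.  Malformed
rows are reported with their line number.  Writers never emit timestamps,
so re-running a stage on identical inputs yields byte-identical files.

Formats:

* ladder TSV: ``rank  taxon  age_mya`` (a default reproducing the 16-stage
  human-lineage ladder ships with the package);
* hits TSV: ``gene_id  species  identity`` with identity a fraction in
  [0, 1] (``62%`` or ``62`` are rejected with a pointer to the format);
* species map TSV: ``species  rank``;
* universe TSV: ``gene_id  pai  di  is_gpcr  is_brain_specific
  is_development  ligand_type  go_terms`` (go_terms semicolon-joined;
  empty pai/di mean missing);
* set file: one gene id per line under a ``# set: <name>`` header;
* codon FASTA: two aligned records per file (focal CDS first).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .divergence import DEFAULT_COMPARATORS, DEFAULT_NEUTRALITY_BAND, PairwiseCodonAlignment
from .genesets import GeneRecord, GeneSet
from .strata import DEFAULT_LADDER_ROWS, StratumLadder

__all__ = [
    "PipelineConfig",
    "read_ladder",
    "write_ladder",
    "read_species_map",
    "write_species_map",
    "read_hits",
    "write_hits",
    "read_universe",
    "write_universe",
    "universe_records",
    "read_gene_set",
    "write_gene_set",
    "read_fasta_pair",
    "read_alignment_manifest",
    "write_dnds_table",
    "write_di_table",
]

UNIVERSE_COLUMNS = [
    "gene_id", "pai", "di", "is_gpcr", "is_brain_specific",
    "is_development", "ligand_type", "go_terms",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full analysis.

    ``identity_threshold`` is the closed lower bound on ortholog identity
    for age assignment; ``di_cut`` the inclusive low-DI threshold;
    ``neutrality_band`` the DI interval classified as neutral;
    ``pai_focus_rank`` the ladder stage tested for enrichment (the
    vertebrate stage by default) and ``pai_focus_ranks_alt`` the stage
    group tested for the non-GPCR receptor subset.
    """

    identity_threshold: float = 0.5
    di_cut: float = 0.25
    neutrality_band: tuple[float, float] = DEFAULT_NEUTRALITY_BAND
    alpha_tiers: tuple[float, ...] = (0.05, 0.01, 0.001)
    comparator_species: tuple[str, ...] = DEFAULT_COMPARATORS
    pai_focus_rank: int = 6
    pai_focus_ranks_alt: tuple[int, ...] = (7, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError(f"identity_threshold must be in (0, 1], got {self.identity_threshold}")
        if self.di_cut <= 0:
            raise ValueError(f"di_cut must be > 0, got {self.di_cut}")
        low, high = self.neutrality_band
        if not 0 <= low < high:
            raise ValueError(f"invalid neutrality_band {self.neutrality_band}")
        if sorted(self.alpha_tiers, reverse=True) != list(self.alpha_tiers):
            raise ValueError("alpha_tiers must be sorted decreasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (or JSON — a YAML subset) mapping."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("neutrality_band", "alpha_tiers", "comparator_species", "pai_focus_ranks_alt"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _meta_line(config: PipelineConfig | None = None) -> str:
    line = f"# phylodi {__version__}"
    if config is not None:
        line += f" config={config.config_hash()}"
    return line + "\n"


# ---------------------------------------------------------------------------
# ladder and species map


def read_ladder(path: str | Path) -> StratumLadder:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["rank", "taxon", "age_mya"], path)
    entries = tuple(
        (int(r), str(t), float(a)) for r, t, a in df[["rank", "taxon", "age_mya"]].itertuples(index=False)
    )
    return StratumLadder(entries)


def write_ladder(ladder: StratumLadder, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line())
        fh.write("rank\ttaxon\tage_mya\n")
        for rank, taxon, age in ladder.entries:
            fh.write(f"{rank}\t{taxon}\t{age:g}\n")


def default_ladder_path() -> Path:
    """Path of the shipped ladder TSV (16-stage human lineage)."""
    return Path(__file__).parent / "data" / "stratum_ladder.tsv"


def read_species_map(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["species", "rank"], path)
    return {str(s): int(r) for s, r in df[["species", "rank"]].itertuples(index=False)}


def write_species_map(mapping: dict[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line())
        fh.write("species\trank\n")
        for species, rank in sorted(mapping.items()):
            fh.write(f"{species}\t{rank}\n")


# ---------------------------------------------------------------------------
# hits


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a hits table, validating identities as fractions in [0, 1]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "species": str})
    _require_columns(df, ["gene_id", "species", "identity"], path)
    try:
        identity = pd.to_numeric(df["identity"], errors="raise")
    except (ValueError, TypeError):
        bad = df[pd.to_numeric(df["identity"], errors="coerce").isna()].iloc[0]
        raise ValueError(
            f"{path}: identity {bad['identity']!r} for {bad['gene_id']} is not a "
            "fraction; expected a dot-decimal number in [0, 1] (e.g. 0.62, not 62%)"
        ) from None
    df["identity"] = identity.astype(float)
    out_of_range = df[(df["identity"] < 0) | (df["identity"] > 1)]
    if len(out_of_range):
        bad = out_of_range.iloc[0]
        line = int(bad.name) + 2  # header occupies line 1
        raise ValueError(
            f"{path}:{line}: identity {bad['identity']} outside [0, 1]; "
            "expected a fraction, not a percentage"
        )
    return df


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line())
        hits.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# universe


def read_universe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"gene_id": str, "ligand_type": str, "go_terms": str},
        keep_default_na=True,
    )
    _require_columns(df, UNIVERSE_COLUMNS, path)
    unknown = [c for c in df.columns if c not in UNIVERSE_COLUMNS]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    df["pai"] = pd.to_numeric(df["pai"], errors="raise").astype("Int64")
    df["di"] = pd.to_numeric(df["di"], errors="raise").astype(float)
    for col in ("is_gpcr", "is_brain_specific", "is_development"):
        df[col] = df[col].astype(int).astype(bool)
    for col in ("ligand_type", "go_terms"):
        df[col] = df[col].fillna("")
    return df


def write_universe(universe: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None) -> None:
    df = universe.copy()
    for col in ("is_gpcr", "is_brain_specific", "is_development"):
        df[col] = df[col].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def universe_records(universe: pd.DataFrame) -> list[GeneRecord]:
    """Materialise a universe table as GeneRecord objects."""
    records = []
    for row in universe.itertuples(index=False):
        pai = None if pd.isna(row.pai) else int(row.pai)
        di = None if pd.isna(row.di) else float(row.di)
        terms = tuple(t for t in str(row.go_terms or "").split(";") if t)
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                pai=pai,
                di=di,
                is_gpcr=bool(row.is_gpcr),
                is_brain_specific=bool(row.is_brain_specific),
                is_development=bool(row.is_development),
                ligand_type=(row.ligand_type or None),
                go_terms=terms,
            )
        )
    return records


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path: str | Path) -> GeneSet:
    name = Path(path).stem
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# set:"):
                name = line.split(":", 1)[1].strip()
            elif line and not line.startswith("#"):
                ids.append(line)
    return GeneSet.from_ids(name, ids)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# set: {gene_set.name}\n")
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


# ---------------------------------------------------------------------------
# codon alignments


def read_fasta_pair(
    path: str | Path, gene_id: str | None = None, species_label: str | None = None
) -> PairwiseCodonAlignment:
    """Read a two-record codon-aligned FASTA (focal sequence first)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, found {len(records)}")
    a, b = records
    for rec in records:
        if len(rec.seq) % 3:
            raise ValueError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)}, not divisible by 3"
            )
    return PairwiseCodonAlignment.from_sequences(
        gene_id or a.id, species_label or b.id, str(a.seq), str(b.seq)
    )


def read_alignment_manifest(path: str | Path) -> list[PairwiseCodonAlignment]:
    """Read a manifest TSV: ``gene_id  species  path_a  path_b``.

    Each row names one single-record FASTA per sequence; if ``path_b`` is
    empty, ``path_a`` must hold both aligned records.  Relative paths are
    resolved against the manifest's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    _require_columns(df, ["gene_id", "species", "path_a"], path)
    alignments = []
    for row in df.itertuples(index=False):
        path_a = base / row.path_a
        path_b = getattr(row, "path_b", "")
        if path_b:
            rec_a = next(SeqIO.parse(str(path_a), "fasta"))
            rec_b = next(SeqIO.parse(str(base / path_b), "fasta"))
            aln = PairwiseCodonAlignment.from_sequences(
                row.gene_id, row.species, str(rec_a.seq), str(rec_b.seq)
            )
        else:
            aln = read_fasta_pair(path_a, gene_id=row.gene_id, species_label=row.species)
        alignments.append(aln)
    return alignments


def write_fasta_pair(aln: PairwiseCodonAlignment, path: str | Path) -> None:
    seq_a = "".join(a for a, _ in aln.columns)
    seq_b = "".join(b for _, b in aln.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{aln.gene_id}\n{seq_a}\n>{aln.species_label}\n{seq_b}\n")


# ---------------------------------------------------------------------------
# result tables


def write_dnds_table(estimates: Iterable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line())
        fh.write("gene_id\tspecies\tN_sites\tS_sites\tNd\tSd\tdN\tdS\tratio\n")
        for e in estimates:
            ratio = "" if e.ratio is None else f"{e.ratio:.6g}"
            fh.write(
                f"{e.gene_id}\t{e.species_label}\t{e.N_sites:.6g}\t{e.S_sites:.6g}\t"
                f"{e.Nd:.6g}\t{e.Sd:.6g}\t{e.dN:.6g}\t{e.dS:.6g}\t{ratio}\n"
            )


def write_di_table(records: Iterable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line())
        fh.write("gene_id\tdi\tn_used\tselection_class\n")
        for r in records:
            di = "" if r.di is None else f"{r.di:.6g}"
            fh.write(f"{r.gene_id}\t{di}\t{r.n_used}\t{r.selection_class}\n")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
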