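"""Readers and writers for the formats the pipeline touches.

FASTA via Biopython; GFF3 / BED / TSV via pandas.  All tables are written
with ``#``-prefixed provenance comment lines followed by a tab-separated
header, and every writer's output round-trips through the matching reader.

Focus tables carry the number of SCs scored per chromosome in header
comments (``# n_cells <chrom> <N>``) because cells with zero foci on a
chromosome have no rows yet still count toward N.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .association import AssociationResult, stars
from .coordinates import ChromosomeModel, HomologyMap, HomologyPair, IntervalGrid
from .features import CpGIsland, FeatureTrack
from .recmap import FOCUS_COLUMNS, FocusTable, RecombinationTrack

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_starts",
    "write_gff3",
    "read_bed_starts",
    "write_grid_bed",
    "write_cgi_bed",
    "read_cgi_bed",
    "read_focus_table",
    "write_focus_table",
    "write_recombination_tracks",
    "read_recombination_tracks",
    "write_feature_tracks",
    "read_feature_tracks",
    "write_association_results",
    "read_association_results",
    "read_chromosome_config",
    "write_chromosome_config",
    "write_truth_json",
]


def _provenance(extra: Optional[Mapping] = None) -> list[str]:
    lines = [f"# recland {__version__}"]
    if extra:
        digest = hashlib.sha1(
            json.dumps(extra, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        for k, v in extra.items():
            lines.append(f"# {k}: {v}")
        lines.append(f"# config_hash: {digest}")
    return lines


def _write_table(path, df: pd.DataFrame, comments: Iterable[str]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in comments:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------- sequences


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------- annotation


def read_gene_starts(path) -> dict[str, np.ndarray]:
    """Gene start positions per chromosome from GFF3 or BED (by extension).

    The lower genomic coordinate is used uniformly for both strands.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed"}:
        return read_bed_starts(path)
    gff = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"seqid": str},
    )
    genes = gff[gff["type"] == "gene"]
    out: dict[str, np.ndarray] = {}
    for chrom, sub in genes.groupby("seqid"):
        # GFF3 is 1-based inclusive; convert the lower bound to 0-based
        out[str(chrom)] = np.sort(sub["start"].to_numpy(dtype=np.int64) - 1)
    return out


def write_gff3(path, gene_starts: Mapping[str, Sequence[int]], gene_length: int = 1000) -> None:
    """Write minimal gene features (1-based inclusive coordinates)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in gene_starts:
            for i, s in enumerate(gene_starts[chrom]):
                s = int(s)
                fh.write(
                    f"{chrom}\trecland_sim\tgene\t{s + 1}\t{s + gene_length}\t.\t+\t.\t"
                    f"ID=gene:{chrom}.{i + 1}\n"
                )


def read_bed_starts(path) -> dict[str, np.ndarray]:
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    return {
        str(chrom): np.sort(sub["start"].to_numpy(dtype=np.int64))
        for chrom, sub in bed.groupby("chrom")
    }


def write_grid_bed(path, grids: Mapping[str, IntervalGrid] | IntervalGrid) -> None:
    """Export one or more grids as BED3."""
    if isinstance(grids, IntervalGrid):
        grids = {grids.chromosome: grids}
    with Path(path).open("w") as fh:
        for grid in grids.values():
            for start, end in grid:
                fh.write(f"{grid.chromosome}\t{start}\t{end}\n")


def write_cgi_bed(path, islands: Iterable[CpGIsland]) -> None:
    """BED4 with obs/exp CpG carried in the name field."""
    with Path(path).open("w") as fh:
        for isl in islands:
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t"
                f"gc={isl.gc_fraction:.4f};oe={isl.obs_exp_cpg:.4f}\n"
            )


def read_cgi_bed(path) -> list[CpGIsland]:
    islands = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            fields = dict(kv.split("=") for kv in name.split(";"))
            islands.append(
                CpGIsland(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    gc_fraction=float(fields["gc"]),
                    obs_exp_cpg=float(fields["oe"]),
                )
            )
    return islands


# -------------------------------------------------------------- focus table


def read_focus_table(path) -> FocusTable:
    """Read the one-row-per-focus TSV dialect (with ``# n_cells`` comments)."""
    path = Path(path)
    n_cells: dict[str, int] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 3 and parts[0] == "n_cells":
                n_cells[parts[1]] = int(parts[2])
    data = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"cell_id": str, "chromosome": str, "position_unit": str},
    )
    if data.empty:
        raise ValueError(f"focus table {path} contains no focus records")
    return FocusTable(data=data[FOCUS_COLUMNS], n_cells=n_cells)


def write_focus_table(path, table: FocusTable, extra: Optional[Mapping] = None) -> None:
    comments = _provenance(extra)
    for chrom in sorted(set(table.n_cells) | set(table.chromosomes())):
        comments.append(f"# n_cells {chrom} {table.cells_scored(chrom)}")
    _write_table(path, table.data[FOCUS_COLUMNS], comments)


# -------------------------------------------------------------------- tracks


def write_recombination_tracks(
    path, tracks: Mapping[str, RecombinationTrack], extra: Optional[Mapping] = None
) -> None:
    frames = []
    comments = _provenance(extra)
    for chrom, t in tracks.items():
        comments.append(f"# n_cells {chrom} {t.n_cells}")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": t.grid.starts,
                    "end": t.grid.ends,
                    "n_foci": t.foci,
                    "cM": t.cM,
                    "rate_cM_per_Mb": t.rate,
                }
            )
        )
    _write_table(path, pd.concat(frames, ignore_index=True), comments)


def read_recombination_tracks(path) -> dict[str, RecombinationTrack]:
    from .coordinates import IntervalGrid

    path = Path(path)
    n_cells: dict[str, int] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 3 and parts[0] == "n_cells":
                n_cells[parts[1]] = int(parts[2])
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out: dict[str, RecombinationTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        interval_size = int(sub["end"].iloc[0] - sub["start"].iloc[0]) if len(sub) > 1 else int(
            sub["end"].iloc[-1]
        )
        grid = IntervalGrid(
            chromosome=str(chrom),
            total_length=int(sub["end"].iloc[-1]),
            interval_size=interval_size,
        )
        out[str(chrom)] = RecombinationTrack(
            grid=grid,
            foci=sub["n_foci"].to_numpy(dtype=np.int64),
            n_cells=n_cells.get(str(chrom), 0),
            cM=sub["cM"].to_numpy(dtype=float),
            rate=sub["rate_cM_per_Mb"].to_numpy(dtype=float),
        )
    return out


def write_feature_tracks(
    path, tracks: Mapping[str, FeatureTrack], extra: Optional[Mapping] = None
) -> None:
    frames = []
    for chrom, t in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": t.grid.starts,
                    "end": t.grid.ends,
                    "gc": t.gc,
                    "cgi_count": t.cgi_count,
                    "gene_count": t.gene_count,
                    "gene_pct": t.gene_pct,
                }
            )
        )
    _write_table(path, pd.concat(frames, ignore_index=True), _provenance(extra))


def read_feature_tracks(path) -> dict[str, FeatureTrack]:
    from .coordinates import IntervalGrid

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out: dict[str, FeatureTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        interval_size = int(sub["end"].iloc[0] - sub["start"].iloc[0]) if len(sub) > 1 else int(
            sub["end"].iloc[-1]
        )
        grid = IntervalGrid(
            chromosome=str(chrom),
            total_length=int(sub["end"].iloc[-1]),
            interval_size=interval_size,
        )
        out[str(chrom)] = FeatureTrack(
            grid=grid,
            gc=sub["gc"].to_numpy(dtype=float),
            cgi_count=sub["cgi_count"].to_numpy(dtype=np.int64),
            gene_count=sub["gene_count"].to_numpy(dtype=np.int64),
            gene_pct=sub["gene_pct"].to_numpy(dtype=float),
        )
    return out


# -------------------------------------------------------------- associations


def write_association_results(
    path, results: Sequence[AssociationResult], extra: Optional[Mapping] = None
) -> None:
    df = pd.DataFrame(
        {
            "scope": [r.chromosome for r in results],
            "feature": [r.feature for r in results],
            "rho": [r.rho if r.rho is not None else np.nan for r in results],
            "p_value": [r.p_value if r.p_value is not None else np.nan for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "zero_excluded": [r.zero_excluded for r in results],
            "stars": [stars(r.p_value) for r in results],
            "note": [r.note for r in results],
        }
    )
    _write_table(path, df, _provenance(extra))


def read_association_results(path) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"scope": str, "feature": str})
    results = []
    for row in df.itertuples(index=False):
        rho = None if pd.isna(row.rho) else float(row.rho)
        p = None if pd.isna(row.p_value) else float(row.p_value)
        results.append(
            AssociationResult(
                chromosome=row.scope,
                feature=row.feature,
                rho=rho,
                p_value=p,
                n_pairs=int(row.n_pairs),
                zero_excluded=bool(row.zero_excluded),
                significant=bool(p is not None and p < 0.05),
                note="" if pd.isna(row.note) else str(row.note),
            )
        )
    return results


# --------------------------------------------------------------------- config


def read_chromosome_config(path) -> tuple[dict[str, ChromosomeModel], HomologyMap]:
    """YAML config: per-chromosome models plus an optional homology section."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    chroms: dict[str, ChromosomeModel] = {}
    for entry in cfg.get("chromosomes", []):
        model = ChromosomeModel(
            name=str(entry["name"]),
            assembly_length=int(entry["assembly_length"]),
            mean_sc_length=entry.get("mean_sc_length"),
            centromere_position=entry.get("centromere_position"),
            orientation=entry.get("orientation", "forward"),
        )
        chroms[model.name] = model
    pairs = [
        HomologyPair(
            a_chrom=str(p["a_chrom"]),
            b_chrom=str(p["b_chrom"]),
            a_start=p.get("a_start"),
            a_end=p.get("a_end"),
            b_start=p.get("b_start"),
            b_end=p.get("b_end"),
            inverted=bool(p.get("inverted", False)),
        )
        for p in cfg.get("homology", [])
    ]
    return chroms, HomologyMap(pairs=pairs)


def write_chromosome_config(
    path, chroms: Mapping[str, ChromosomeModel], homology: Optional[HomologyMap] = None
) -> None:
    cfg: dict = {
        "chromosomes": [
            {
                "name": c.name,
                "assembly_length": c.assembly_length,
                "mean_sc_length": c.mean_sc_length,
                "centromere_position": c.centromere_position,
                "orientation": c.orientation,
            }
            for c in chroms.values()
        ]
    }
    if homology and homology.pairs:
        cfg["homology"] = [
            {
                "a_chrom": p.a_chrom,
                "b_chrom": p.b_chrom,
                "a_start": p.a_start,
                "a_end": p.a_end,
                "b_start": p.b_start,
                "b_end": p.b_end,
                "inverted": p.inverted,
            }
            for p in homology.pairs
        ]
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_truth_json(path, truth: Mapping) -> None:
    with Path(path).open("w") as fh:
        json.dump(truth, fh, indent=1)
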