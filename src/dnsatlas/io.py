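"""Readers and writers for the genomic file formats the pipeline consumes.

All coordinates on disk follow the conventions of each format (BED and
bedGraph 0-based half-open, GFF3 1-based closed); everything in memory is
0-based half-open. Readers validate coordinates against the assembly and
report parse errors with line numbers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BinTrack
from .genome import (ChromosomeSegments, GenomeAssembly, GenomeError,
                     GenomicInterval, GeneModel, TEAnnotation, SEGMENT_LABELS)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- assemblies

def read_assembly(path, subgenome_regex=None) -> GenomeAssembly:
    """Read a chrom-sizes TSV (name <tab> length; .fai files also work)."""
    chroms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected name<TAB>length")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError:
                raise ParseError(f"{path}:{ln}: bad length {parts[1]!r}") from None
    kwargs = {} if subgenome_regex is None else {"subgenome_regex": subgenome_regex}
    return GenomeAssembly(chroms, **kwargs)


def write_assembly(assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for name in assembly:
            fh.write(f"{name}\t{assembly.length(name)}\n")


# ----------------------------------------------------------------------- BED

def read_intervals(path, assembly: GenomeAssembly) -> list[GenomicInterval]:
    """Read BED3/BED6 to validated intervals, preserving file order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                assembly.validate(iv)
            except GenomeError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
            out.append(iv)
    return out


def write_intervals(intervals, path, names=None, scores=None) -> None:
    """Write BED3 (or BED6 when names/scores given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ----------------------------------------------------------------- gene GFF3

def read_gene_models(path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Read gene models from GFF3 (gene + CDS features) or a 8-column TSV.

    GFF3: the CDS span of a gene is the union (envelope) of its CDS
    features, matched by the Parent/ID attribute chain. Genes without any
    CDS are skipped with a warning; a CDS outside its gene span is an error.
    TSV columns: gene_id, chrom, start, end, strand, cds_start, cds_end,
    confidence (0-based half-open).
    """
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or (head and head.split("\t")[2:3] == ["gene"]):
        return _read_gff3(path, assembly)
    if head.startswith("gene_id"):
        return _read_gene_tsv(path, assembly)
    # fall back on extension sniffing
    if str(path).endswith((".gff", ".gff3")):
        return _read_gff3(path, assembly)
    return _read_gene_tsv(path, assembly)


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path, assembly) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    cds: dict[str, list[tuple[int, int]]] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{ln}: GFF3 needs 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            try:
                start, end = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{ln}: gene without ID")
                genes[gid] = {"chrom": chrom, "start": start, "end": end,
                              "strand": strand,
                              "confidence": a.get("confidence", "HC"), "line": ln}
                order.append(gid)
            elif ftype == "mRNA":
                if "ID" in a and "Parent" in a:
                    mrna_parent[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                parent = a.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{ln}: CDS without Parent")
                cds.setdefault(parent, []).append((start, end))
    out: list[GeneModel] = []
    for gid in order:
        g = genes[gid]
        spans = list(cds.get(gid, []))
        for mid, parent in mrna_parent.items():
            if parent == gid:
                spans.extend(cds.get(mid, []))
        if not spans:
            warnings.warn(f"gene {gid} has no CDS features; skipped")
            continue
        cs, ce = min(s for s, _ in spans), max(e for _, e in spans)
        if cs < g["start"] or ce > g["end"]:
            raise ParseError(f"{path}: gene {gid}: CDS outside gene span")
        iv = GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"])
        try:
            assembly.validate(iv)
        except GenomeError as e:
            raise ParseError(f"{path}: gene {gid}: {e}") from None
        out.append(GeneModel(gid, iv, cs, ce, g["confidence"]))
    return out


def _read_gene_tsv(path, assembly) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        iv = assembly.validate(GenomicInterval(row.chrom, int(row.start),
                                               int(row.end), row.strand))
        out.append(GeneModel(row.gene_id, iv, int(row.cds_start),
                             int(row.cds_end), getattr(row, "confidence", "HC")))
    return out


def write_gene_models_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\tdnsatlas\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\tID={g.gene_id};confidence={g.confidence}\n")
            fh.write(f"{iv.chrom}\tdnsatlas\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                     f"{iv.strand}\t0\tParent={g.gene_id}\n")


# ------------------------------------------------------------------ TE BED

def read_te_annotations(path, assembly, cereba_families=()) -> list[TEAnnotation]:
    """Read a TE BED whose name column holds SUPERFAMILY_family names.

    Cereba membership is configured as a set of family names (the Cereba
    retrotransposon is an LTR family, not a coordinate list).
    """
    cereba = set(cereba_families)
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: TE BED needs >= 4 columns (name)")
            try:
                iv = assembly.validate(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except (ValueError, GenomeError) as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
            fam = parts[3]
            out.append(TEAnnotation(iv, fam, is_cereba=fam in cereba))
    return out


def write_te_annotations(tes, path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.family}\n")


# --------------------------------------------------------------- bedGraph

def write_track(track: BinTrack, path) -> None:
    """Write a BinTrack as bedGraph, merging consecutive equal-valued bins.

    Values use 6 significant digits; coordinates 0-based half-open.
    """
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.assembly:
            vals = track.data[chrom]
            L = track.assembly.length(chrom)
            if vals.size == 0:
                continue
            formatted = [_fmt6(v) for v in vals]
            run_start = 0
            for i in range(1, len(formatted) + 1):
                if i == len(formatted) or formatted[i] != formatted[run_start]:
                    start = run_start * w
                    end = min(i * w, L)
                    fh.write(f"{chrom}\t{start}\t{end}\t{formatted[run_start]}\n")
                    run_start = i


def _fmt6(v: float) -> str:
    if v == 0:
        return "0"
    s = f"{v:.6g}"
    return "0" if s in ("-0", "0.0", "-0.0") else s


def read_track(path, assembly: GenomeAssembly, bin_width: int = 10) -> BinTrack:
    """Read a bedGraph into a BinTrack (intervals must align to bins)."""
    track = BinTrack(assembly, bin_width)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: bedGraph needs 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in assembly:
                raise ParseError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start % bin_width:
                raise ParseError(f"{path}:{ln}: interval not aligned to {bin_width}-bp bins")
            b0 = start // bin_width
            b1 = (end - 1) // bin_width
            track.data[chrom][b0:b1 + 1] = value
    return track


# ----------------------------------------------------------------- segments

def read_segments(path, assembly: GenomeAssembly) -> ChromosomeSegments:
    """Read the per-chromosome segment table.

    TSV columns: chrom, label (R1/R2a/C/R2b/R3/CENH3), start, end.
    """
    df = pd.read_csv(path, sep="\t")
    segs = ChromosomeSegments(assembly)
    for chrom, grp in df.groupby("chrom", sort=False):
        rows = {r.label: GenomicInterval(chrom, int(r.start), int(r.end))
                for r in grp.itertuples(index=False)}
        cenh3 = rows.pop("CENH3", None)
        if cenh3 is None:
            raise ParseError(f"{path}: chromosome {chrom} lacks a CENH3 row")
        segs.set_chromosome(chrom, rows, cenh3)
    return segs


def write_segments(segments: ChromosomeSegments, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlabel\tstart\tend\n")
        for chrom in segments.chromosomes:
            for label in SEGMENT_LABELS:
                iv = segments.segment(chrom, label)
                fh.write(f"{chrom}\t{label}\t{iv.start}\t{iv.end}\n")
            c = segments.cenh3(chrom)
            fh.write(f"{chrom}\tCENH3\t{c.start}\t{c.end}\n")


# ----------------------------------------------------- expression / triplets

def read_expression(path) -> pd.Series:
    """gene_id -> mean tpm. Columns: gene_id, tpm."""
    df = pd.read_csv(path, sep="\t")
    s = df.set_index("gene_id")["tpm"].astype(float)
    if (s < 0).any():
        raise ParseError(f"{path}: negative tpm values")
    return s


def write_expression(tpm: pd.Series, path) -> None:
    tpm.rename("tpm").rename_axis("gene_id").to_frame().to_csv(path, sep="\t")


def read_triplets(path) -> pd.DataFrame:
    """Homoeologous triplet table with columns gene_A, gene_B, gene_D."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_A", "gene_B", "gene_D"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df[["gene_A", "gene_B", "gene_D"]]


# ------------------------------------------------------------------ footprints

def write_footprints(footprints, bed_path, tsv_path=None) -> None:
    """BED6 with name MSF|MRF and score = round(mean_dns * 1000); the
    full-precision means go to a sidecar TSV."""
    with open(bed_path, "w") as fh:
        for fp in footprints:
            iv = fp.interval
            score = int(round(fp.mean_dns * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fp.kind}\t{score}\t.\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("chrom\tstart\tend\tkind\tmean_dns\tmean_z\treplicates\n")
            for fp in footprints:
                iv = fp.interval
                reps = ",".join(str(r) for r in sorted(fp.replicate_support))
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fp.kind}\t"
                         f"{fp.mean_dns:.6g}\t{fp.mean_z:.6g}\t{reps}\n")


# ----------------------------------------------------------- SNPs/phenotypes

def read_snps(path):
    """Minimal SNP TSV: chrom, pos, then one 0/1/2/NA column per individual.

    Returns (positions DataFrame[chrom,pos], genotype matrix individuals x
    SNPs with nan for missing, individual ids).
    """
    df = pd.read_csv(path, sep="\t")
    pos = df[["chrom", "pos"]].copy()
    ind = [c for c in df.columns if c not in ("chrom", "pos")]
    G = df[ind].to_numpy(dtype=float).T
    return pos, G, ind


def write_snps(pos: pd.DataFrame, G: np.ndarray, individuals, path) -> None:
    cols = {"chrom": pos["chrom"].to_numpy(), "pos": pos["pos"].to_numpy()}
    for i, name in enumerate(individuals):
        cols[name] = ["NA" if np.isnan(v) else int(v) for v in G[i]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """individual-indexed trait table (first column = individual id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
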