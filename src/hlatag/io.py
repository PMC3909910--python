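"""Readers, writers and model persistence.

On-disk formats are deliberately boring: unphased biallelic VCF (or a
sample-by-SNP 0/1/2 TSV matrix plus a marker map), a long-format HLA typing
TSV (sample / locus / allele1 / allele2), a JSON model file with a format
version, and TSV reports.  All coordinates are 1-based (VCF convention);
genotypes count the declared alternate allele; missing calls are "./." in
VCF and "NA" or "-9" in TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeFrequencyTable, normalize_hla, pair_key

__all__ = [
    "CohortDataset",
    "load_cohort",
    "save_cohort",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1
_TSV_MISSING = {"NA", "-9", ""}


@dataclass
class CohortDataset:
    """A cohort: genotype matrix + marker map + HLA typing table.

    ``genotypes`` is samples x markers with values 0/1/2 (alternate-allele
    count) or −1 for missing.  ``markers`` has columns id/chrom/pos (positions
    strictly increasing within a chromosome).  ``hla`` is long-format with
    columns sample/locus/allele1/allele2, allele codes normalised to 4
    digits; loci may be typed for a subset of samples.  Simulated datasets
    additionally carry the hidden phased truth.
    """

    samples: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray
    hla: pd.DataFrame
    truth_haplotypes: np.ndarray | None = None  # n x 2 x m, per-gamete alleles
    truth_alleles: np.ndarray | None = None  # n x 2 allele codes
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError("genotype matrix does not match samples x markers")
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicated marker id")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("marker positions must increase within a chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def loci(self) -> list[str]:
        return sorted(self.hla["locus"].unique())

    def marker_ids(self) -> list[str]:
        return self.markers["id"].tolist()

    def hla_pairs(self, locus: str) -> tuple[list[int], list[tuple[str, str]]]:
        """Indices of samples typed at *locus* and their unordered code pairs."""
        sub = self.hla[self.hla["locus"] == locus]
        idx_of = {s: k for k, s in enumerate(self.samples)}
        rows, pairs = [], []
        for _, r in sub.iterrows():
            if r["sample"] not in idx_of:
                raise KeyError(f"typed sample {r['sample']!r} absent from genotypes")
            rows.append(idx_of[r["sample"]])
            pairs.append(pair_key(str(r["allele1"]), str(r["allele2"])))
        return rows, pairs

    def subset_markers(self, ids) -> "CohortDataset":
        keep = self.markers["id"].isin(set(ids)).to_numpy()
        return CohortDataset(
            samples=list(self.samples),
            markers=self.markers.loc[keep].reset_index(drop=True),
            genotypes=self.genotypes[:, keep].copy(),
            hla=self.hla.copy(),
            ref=self.ref,
            alt=self.alt,
        )

    def equals(self, other: "CohortDataset") -> bool:
        return (
            self.samples == other.samples
            and self.markers[["id", "chrom", "pos"]].equals(other.markers[["id", "chrom", "pos"]])
            and np.array_equal(self.genotypes, other.genotypes)
            and self.hla.sort_values(["sample", "locus"]).reset_index(drop=True).equals(
                other.hla.sort_values(["sample", "locus"]).reset_index(drop=True)
            )
        )


# ---------------------------------------------------------------------------
# Cohort writers
# ---------------------------------------------------------------------------


def _write_vcf(ds: CohortDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hlatag\n")
        for chrom in ds.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for k, row in enumerate(ds.markers.itertuples(index=False)):
            calls = "\t".join(gt_map[int(g)] for g in ds.genotypes[:, k])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{ds.ref}\t{ds.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def save_cohort(ds: CohortDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a cohort as VCF + marker-map TSV + HLA typing TSV (+ truth).

    Returns the mapping of part name to path.  The truth sidecar (one row per
    gamete: sample, hap index, HLA allele, SNP alleles as a 0/1 string) is
    written only for simulated datasets that carry it.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.parent / (prefix.name + ".vcf"),
        "map": prefix.parent / (prefix.name + ".map.tsv"),
        "hla": prefix.parent / (prefix.name + ".hla.tsv"),
    }
    _write_vcf(ds, paths["vcf"])
    ds.markers[["id", "chrom", "pos"]].to_csv(paths["map"], sep="\t", index=False)
    ds.hla.to_csv(paths["hla"], sep="\t", index=False)
    if ds.truth_haplotypes is not None and ds.truth_alleles is not None:
        paths["truth"] = prefix.parent / (prefix.name + ".truth.tsv")
        with open(paths["truth"], "w") as fh:
            fh.write("sample\tgamete\thla\tsnp_alleles\n")
            for s, sample in enumerate(ds.samples):
                for g in range(2):
                    alleles = "".join(str(int(x)) for x in ds.truth_haplotypes[s, g])
                    fh.write(f"{sample}\t{g}\t{ds.truth_alleles[s, g]}\t{alleles}\n")
    return paths


# ---------------------------------------------------------------------------
# Cohort readers
# ---------------------------------------------------------------------------


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    cols = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} is not supported; "
                "split or drop it first"
            )
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
        col = np.empty(len(samples), dtype=np.int8)
        for s, g in enumerate(v.genotypes):  # [a1, a2, phased]; phase ignored
            a1, a2 = g[0], g[1]
            col[s] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
        cols.append(col)
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    geno = np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    return samples, markers, geno, (refs[0] if refs else "A"), (alts[0] if alts else "G")


def _read_matrix(path: Path, map_path: Path):
    markers = pd.read_csv(map_path, sep="\t", dtype={"id": str, "chrom": str, "pos": int})
    mat = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if list(mat.columns) != markers["id"].tolist():
        mat = mat[markers["id"].tolist()]  # raises on unknown marker
    geno = np.full(mat.shape, MISSING, dtype=np.int8)
    vals = mat.to_numpy()
    for code in ("0", "1", "2"):
        geno[vals == code] = int(code)
    bad = ~np.isin(vals, list(_TSV_MISSING) + ["0", "1", "2"]) & ~pd.isna(vals)
    if bad.any():
        raise ValueError(f"malformed genotype value {vals[bad][0]!r} in {path}")
    return list(mat.index.astype(str)), markers, geno


def _read_typing(path: Path) -> pd.DataFrame:
    hla = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "locus", "allele1", "allele2"}
    if not need <= set(hla.columns):
        raise ValueError(f"typing file {path} must have columns {sorted(need)}")
    rows = []
    for _, r in hla.iterrows():
        a1 = normalize_hla(str(r["allele1"]), locus=r["locus"])
        a2 = normalize_hla(str(r["allele2"]), locus=r["locus"])
        rows.append((r["sample"], a1.locus, a1.code, a2.code))
    return pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])


def load_cohort(
    genotype_path: str | Path,
    typing_path: str | Path,
    map_path: str | Path | None = None,
) -> CohortDataset:
    """Load a cohort from VCF (or TSV matrix + marker map) plus a typing TSV.

    VCF genotypes may be phased or unphased; phase is discarded.  Markers are
    sorted deterministically by (chromosome, position, id).  Typed samples
    must be a subset of genotyped samples.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix in {".vcf", ".gz", ".bcf"}:
        samples, markers, geno, ref, alt = _read_vcf(genotype_path)
    else:
        if map_path is None:
            raise ValueError("TSV genotype matrices need a marker map file")
        samples, markers, geno = _read_matrix(genotype_path, Path(map_path))
        ref, alt = "A", "G"
    order = markers.sort_values(["chrom", "pos", "id"]).index.to_numpy()
    markers = markers.loc[order].reset_index(drop=True)
    geno = geno[:, order]
    hla = _read_typing(Path(typing_path))
    unknown = set(hla["sample"]) - set(samples)
    if unknown:
        raise KeyError(f"typed samples missing from genotype data: {sorted(unknown)[:5]}")
    return CohortDataset(samples=samples, markers=markers, genotypes=geno, hla=hla,
                         ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------


def save_model(model, path: str | Path) -> None:
    """Serialise a prediction model to versioned JSON (round-trip exact).

    Frequencies are stored via Python float repr, which JSON round-trips
    bit-exactly.
    """
    table = model.table
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "locus": model.locus,
        "flank_kb": model.flank_kb,
        "objective": model.objective,
        "n_train": model.n_train,
        "seed": model.seed,
        "marker_ids": table.marker_ids,
        "haplotypes": ["".join(str(int(x)) for x in row) for row in table.haplotypes],
        "hla_codes": table.hla_codes,
        "frequencies": [float(f) for f in table.frequencies],
        "prune_threshold": table.prune_threshold,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`, validating its invariants."""
    from .selection import PredictionModel

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"truncated or malformed model file {path}: {exc}") from exc
    if "format_version" not in doc:
        raise ValueError(f"model file {path} lacks a format_version field")
    if doc["format_version"] > MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {doc['format_version']} is newer than "
            f"supported ({MODEL_FORMAT_VERSION})"
        )
    m = len(doc["marker_ids"])
    haps = np.array(
        [[int(c) for c in row] for row in doc["haplotypes"]], dtype=np.int8
    ).reshape(len(doc["hla_codes"]), m)
    table = HaplotypeFrequencyTable(
        locus=doc["locus"],
        marker_ids=list(doc["marker_ids"]),
        haplotypes=haps,
        hla_codes=list(doc["hla_codes"]),
        frequencies=np.array(doc["frequencies"], dtype=float),
        prune_threshold=float(doc["prune_threshold"]),
    )
    return PredictionModel(
        locus=doc["locus"],
        marker_ids=list(doc["marker_ids"]),
        table=table,
        flank_kb=doc.get("flank_kb"),
        objective=doc.get("objective"),
        n_train=int(doc.get("n_train", 0)),
        seed=doc.get("seed"),
    )
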