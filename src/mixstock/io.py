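"""Genotype containers, file I/O and quality-control filters.

Genotypes are diploid biallelic SNP calls stored as alternate-allele counts
(0, 1, 2) with ``MISSING = -1`` as the missing sentinel.  Locus identity is
carried in names of the form ``LG{nn}_{position}_{suffix}`` where the suffix
encodes the panel class of the marker (``SEL`` diagnostic, ``CAN`` candidate
gene, ``I{nn}`` chromosomal inversion, ``SEX`` sex-linked).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1


class PanelClass(str, Enum):
    DIAGNOSTIC = "diagnostic"
    CANDIDATE = "candidate"
    INVERSION = "inversion"
    SEX = "sex"


_LOCUS_RE = re.compile(
    r"^LG(?P<lg>\d{2})_(?P<pos>\d+)_(?P<suffix>SEL|CAN|SEX|I\d{2})(?P<extra>[A-Za-z0-9_]*)$"
)

_SUFFIX_CLASS = {"SEL": PanelClass.DIAGNOSTIC, "CAN": PanelClass.CANDIDATE, "SEX": PanelClass.SEX}


@dataclass(frozen=True)
class LocusInfo:
    """Identity and genomic context of one biallelic SNP locus."""

    locus_id: str
    linkage_group: int
    position_bp: int
    panel_class: PanelClass
    ref_allele: str = "A"
    alt_allele: str = "G"
    #: which allele is the presumed collinear (non-inverted) arrangement;
    #: set for inversion loci only
    collinear_allele: str | None = None

    def __post_init__(self):
        if not 1 <= self.linkage_group <= 23:
            raise ValueError(f"{self.locus_id}: linkage group {self.linkage_group} outside 1-23")
        if self.position_bp < 1:
            raise ValueError(f"{self.locus_id}: position must be 1-based positive")
        if (self.collinear_allele is not None) != (self.panel_class is PanelClass.INVERSION):
            raise ValueError(
                f"{self.locus_id}: collinear_allele is set iff the locus is an inversion marker"
            )
        if self.collinear_allele not in (None, "ref", "alt"):
            raise ValueError(f"{self.locus_id}: collinear_allele must be 'ref' or 'alt'")

    @classmethod
    def from_locus_id(cls, locus_id: str, **overrides) -> "LocusInfo":
        """Parse ``LG{nn}_{position}_{suffix}`` into a LocusInfo.

        Trailing suffix decorations (``b``, ``_3``, ``_60``) are permitted,
        e.g. ``LG07_20281433_I07b`` or ``LG04_23059256_SEL_60``.
        """
        m = _LOCUS_RE.match(locus_id)
        if m is None:
            raise ValueError(f"locus id {locus_id!r} does not parse as LG{{nn}}_{{pos}}_{{suffix}}")
        suffix = m.group("suffix")
        if suffix.startswith("I"):
            panel_class = PanelClass.INVERSION
            overrides.setdefault("collinear_allele", "ref")
        else:
            panel_class = _SUFFIX_CLASS[suffix]
        kwargs = dict(
            locus_id=locus_id,
            linkage_group=int(m.group("lg")),
            position_bp=int(m.group("pos")),
            panel_class=panel_class,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def make_locus_id(linkage_group: int, position_bp: int, panel_class: PanelClass,
                  inversion_tag: str | None = None) -> str:
    suffix = {
        PanelClass.DIAGNOSTIC: "SEL",
        PanelClass.CANDIDATE: "CAN",
        PanelClass.SEX: "SEX",
        PanelClass.INVERSION: inversion_tag or f"I{linkage_group:02d}",
    }[panel_class]
    return f"LG{linkage_group:02d}_{position_bp:08d}_{suffix}"


class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with per-individual metadata.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers, one per row of ``calls``.
    loci : sequence of LocusInfo
        Unique loci, one per column of ``calls``.
    calls : array (n_individuals, n_loci)
        Alternate-allele counts in {0, 1, 2}; ``MISSING`` (-1) for no-calls.
    metadata : DataFrame, optional
        Indexed by individual id; typically carries ``sampling_unit`` and
        ``year``, plus ``true_origin`` for simulated data.
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[LocusInfo],
                 calls: np.ndarray, metadata: pd.DataFrame | None = None):
        individuals = list(individuals)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(individuals), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(individuals)}, {len(loci)})")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {calls[i, j]} for individual {individuals[i]!r} "
                f"at locus {loci[j].locus_id!r}")
        if len(set(individuals)) != len(individuals):
            dup = pd.Series(individuals).value_counts()
            raise ValueError(f"duplicate individual id {dup.index[0]!r}")
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate locus id {dup.index[0]!r}")
        if metadata is None:
            metadata = pd.DataFrame(index=pd.Index(individuals, name="individual"))
        else:
            metadata = metadata.loc[individuals].copy()
            metadata.index.name = "individual"
        self.individuals = individuals
        self.loci = loci
        self.calls = calls
        self.metadata = metadata

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def locus_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def individual_call_fraction(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def group_codes(self, grouping: str) -> tuple[np.ndarray, list]:
        """Integer group code per individual plus the ordered group labels."""
        if grouping not in self.metadata.columns:
            raise KeyError(f"metadata column {grouping!r} not present")
        values = self.metadata[grouping]
        labels = sorted(values.dropna().unique().tolist())
        lookup = {v: i for i, v in enumerate(labels)}
        codes = np.array([lookup.get(v, -1) for v in values], dtype=np.int64)
        return codes, labels

    def subset(self, individuals: Iterable[str] | np.ndarray | None = None,
               loci: Iterable[str] | np.ndarray | None = None) -> "GenotypeMatrix":
        """Restrict to the given individuals and/or locus ids (or boolean masks)."""
        row_idx = np.arange(self.n_individuals)
        col_idx = np.arange(self.n_loci)
        if individuals is not None:
            if isinstance(individuals, np.ndarray) and individuals.dtype == bool:
                row_idx = np.flatnonzero(individuals)
            else:
                pos = {ind: i for i, ind in enumerate(self.individuals)}
                row_idx = np.array([pos[i] for i in individuals], dtype=int)
        if loci is not None:
            if isinstance(loci, np.ndarray) and loci.dtype == bool:
                col_idx = np.flatnonzero(loci)
            else:
                pos = {lid: j for j, lid in enumerate(self.locus_ids)}
                col_idx = np.array([pos[l] for l in loci], dtype=int)
        return GenotypeMatrix(
            [self.individuals[i] for i in row_idx],
            [self.loci[j] for j in col_idx],
            self.calls[np.ix_(row_idx, col_idx)],
            self.metadata.iloc[row_idx],
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_individuals} individuals x {self.n_loci} loci>"

    # -- tabular round trip ------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the TSV genotype table (metadata columns then locus calls)."""
        df = self.metadata.copy()
        calls = pd.DataFrame(self.calls, index=df.index, columns=self.locus_ids)
        calls = calls.astype(object).where(calls != MISSING, "NA")
        pd.concat([df, calls], axis=1).to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_table(cls, path: str | Path,
                   locus_info: dict[str, LocusInfo] | None = None) -> "GenotypeMatrix":
        """Read the TSV genotype table written by :meth:`to_table`.

        Columns whose names parse as locus ids are genotype calls; the rest
        are individual metadata. ``NA`` maps to missing.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no individuals in table")
        locus_cols = [c for c in df.columns if _LOCUS_RE.match(c)]
        if not locus_cols:
            raise ValueError(f"{path}: no locus columns found")
        meta_cols = [c for c in df.columns if c not in locus_cols]
        loci = [
            (locus_info or {}).get(c) or LocusInfo.from_locus_id(c)
            for c in locus_cols
        ]
        raw = df[locus_cols].replace({"NA": str(MISSING), "": str(MISSING)})
        try:
            calls = raw.astype(np.int8).to_numpy()
        except ValueError as exc:
            raise ValueError(f"{path}: malformed genotype call ({exc})") from exc
        meta = df[meta_cols].copy()
        for col in ("year",):
            if col in meta.columns:
                meta[col] = pd.to_numeric(meta[col], errors="coerce")
        if "length_cm" in meta.columns:
            meta["length_cm"] = pd.to_numeric(meta["length_cm"], errors="coerce")
        meta = meta.replace({"NA": None, "": None})
        return cls(df.index.tolist(), loci, calls, meta)

    # -- VCF ---------------------------------------------------------------

    def to_vcf(self, path: str | Path) -> None:
        """Write genotypes as an uncompressed VCF (one sample column per
        individual, GT field only; linkage groups as contigs)."""
        path = Path(path)
        lgs = sorted({l.linkage_group for l in self.loci})
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=mixstock\n")
            for lg in lgs:
                fh.write(f"##contig=<ID=LG{lg:02d}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individuals) + "\n")
            order = np.lexsort(([l.position_bp for l in self.loci],
                                [l.linkage_group for l in self.loci]))
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j in order:
                loc = self.loci[j]
                gts = "\t".join(gt_str[int(c)] for c in self.calls[:, j])
                fh.write(f"LG{loc.linkage_group:02d}\t{loc.position_bp}\t{loc.locus_id}\t"
                         f"{loc.ref_allele}\t{loc.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path: str | Path,
                 metadata: pd.DataFrame | None = None) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF; GT fields map to alt-allele counts."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        loci: list[LocusInfo] = []
        rows: list[np.ndarray] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic "
                    f"(ALT={rec.ALT})")
            lid = rec.ID
            if lid and _LOCUS_RE.match(lid):
                info = LocusInfo.from_locus_id(lid, ref_allele=rec.REF,
                                               alt_allele=rec.ALT[0])
            else:
                lg = int(re.sub(r"\D", "", rec.CHROM) or 1)
                info = LocusInfo(lid or f"LG{lg:02d}_{rec.POS:08d}_SEL",
                                 lg, rec.POS, PanelClass.DIAGNOSTIC,
                                 rec.REF, rec.ALT[0])
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            g = rec.gt_types
            calls = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING)
            loci.append(info)
            rows.append(calls.astype(np.int8))
        if not loci:
            raise ValueError(f"{path}: no variant records")
        calls = np.stack(rows, axis=1)
        return cls(individuals, loci, calls, metadata)


def read_genotypes(path: str | Path, format: str = "table",
                   metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a genotype dataset from ``table`` (TSV) or ``vcf`` format."""
    if format == "table":
        return GenotypeMatrix.from_table(path)
    if format == "vcf":
        return GenotypeMatrix.from_vcf(path, metadata=metadata)
    raise ValueError(f"unknown format {format!r}; expected 'table' or 'vcf'")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-item removal record from a QC step."""

    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["item", "reason"]))

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def counts(self) -> pd.Series:
        return self.removed["reason"].value_counts()

    def to_tsv(self, path: str | Path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def filter_loci(g: GenotypeMatrix, max_missing_fraction: float = 0.5,
                drop_sex: bool = True, drop_monomorphic: bool = True,
                drop_ids: Iterable[str] = ()) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove low-quality loci.

    Removal rules, applied with fixed precedence so the report is
    deterministic: explicitly listed (e.g. instrument-side poor clustering),
    sex-linked, monomorphic, then missingness strictly above
    ``max_missing_fraction``.  A locus with exactly the threshold fraction of
    missing calls is retained.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    drop_ids = set(drop_ids)
    miss = g.locus_missing_fraction()
    records = []
    keep = np.ones(g.n_loci, dtype=bool)
    for j, loc in enumerate(g.loci):
        obs = g.calls[:, j][g.calls[:, j] != MISSING]
        monomorphic = obs.size == 0 or (obs == obs[0]).all() and obs[0] in (0, 2)
        if loc.locus_id in drop_ids:
            reason = "listed"
        elif drop_sex and loc.panel_class is PanelClass.SEX:
            reason = "sex"
        elif drop_monomorphic and monomorphic:
            reason = "monomorphic"
        elif miss[j] > max_missing_fraction:
            reason = "missingness"
        else:
            continue
        keep[j] = False
        records.append({"item": loc.locus_id, "reason": reason})
    report = FilterReport(pd.DataFrame(records, columns=["item", "reason"]))
    return g.subset(loci=keep), report


def filter_individuals(g: GenotypeMatrix,
                       min_call_fraction: float = 0.5) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals whose non-missing call fraction is strictly below
    ``min_call_fraction`` (an individual exactly at the threshold is kept)."""
    frac = g.individual_call_fraction()
    keep = frac >= min_call_fraction
    records = [{"item": ind, "reason": "low_call_rate"}
               for ind, k in zip(g.individuals, keep) if not k]
    report = FilterReport(pd.DataFrame(records, columns=["item", "reason"]))
    return g.subset(individuals=keep), report


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix, grouping: str | None = None) -> pd.DataFrame:
    """Alternate-allele frequency per (group, locus).

    Returns a DataFrame with columns ``group``, ``locus``, ``p`` and
    ``allele_count`` (= 2 x non-missing individuals).  ``p`` is NaN where a
    group has no non-missing call at a locus.  With ``grouping=None`` the
    whole sample forms one group labelled ``"all"``.
    """
    if grouping is None:
        codes, labels = np.zeros(g.n_individuals, dtype=int), ["all"]
    else:
        codes, labels = g.group_codes(grouping)
    rows = []
    for gi, label in enumerate(labels):
        sub = g.calls[codes == gi]
        ok = sub != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(ok, sub, 0).sum(axis=0) / (2.0 * n), np.nan)
        for j, lid in enumerate(g.locus_ids):
            rows.append({"group": label, "locus": lid,
                         "p": p[j], "allele_count": int(2 * n[j])})
    return pd.DataFrame(rows)


def read_locus_table(path: str | Path) -> dict[str, LocusInfo]:
    """Read a locus-metadata side TSV whose values override what is parsed
    from locus names.

    Columns: ``locus_id`` (required) and any of ``linkage_group``,
    ``position_bp``, ``panel_class``, ``ref_allele``, ``alt_allele``,
    ``collinear_allele``.  Returns a dict usable as the ``locus_info``
    argument of :meth:`GenotypeMatrix.from_table`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "locus_id" not in df.columns:
        raise ValueError(f"{path}: locus metadata table needs a 'locus_id' column")
    out: dict[str, LocusInfo] = {}
    for _, row in df.iterrows():
        overrides: dict = {}
        for col in ("ref_allele", "alt_allele", "collinear_allele"):
            if col in df.columns and pd.notna(row[col]):
                overrides[col] = row[col]
        if "panel_class" in df.columns and pd.notna(row["panel_class"]):
            overrides["panel_class"] = PanelClass(row["panel_class"])
        for col in ("linkage_group", "position_bp"):
            if col in df.columns and pd.notna(row[col]):
                overrides[col] = int(row[col])
        base = LocusInfo.from_locus_id(row["locus_id"])
        fields = {f: getattr(base, f) for f in
                  ("locus_id", "linkage_group", "position_bp", "panel_class",
                   "ref_allele", "alt_allele", "collinear_allele")}
        fields.update(overrides)
        out[row["locus_id"]] = LocusInfo(**fields)
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-style interval file (chrom, start, end; 0-based half-open).

    Chromosome names like ``LG02`` or plain integers are mapped to linkage
    group numbers.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["linkage_group"] = df["chrom"].astype(str).str.extract(r"(\d+)").astype(int)
    return df[["linkage_group", "start", "end"]]
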