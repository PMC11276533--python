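"""Shared data model and readers/writers for genotypes, metadata, and results.

Genotypes are stored as alt-allele dosages (0/1/2) with a dedicated missing
sentinel (:data:`MISSING`, never 0).  Coordinates are 1-based physical
positions; genetic positions in centimorgans come from a 3-column sidecar map
(chrom, pos_bp, cM) or default to 1 cM/Mb.  Sample and variant order are
preserved from input and all joins are by id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

CENSUS_CATEGORIES = ("Black", "Indigenous", "Mixed", "White", "Yellow")
NOT_ANSWERED = "NotAnswered"
WRITE_IN = "write-in"

RELATIONSHIPS = ("head", "spouse", "child", "other_relative", "unrelated")

AGE_GROUPS = ("adolescent", "adult", "older_adult")

#: Portuguese census labels as they appear in questionnaires.
PT_CENSUS = {
    "preta": "Black",
    "preto": "Black",
    "indigena": "Indigenous",
    "parda": "Mixed",
    "pardo": "Mixed",
    "branca": "White",
    "branco": "White",
    "amarela": "Yellow",
    "amarelo": "Yellow",
}


class ParseError(ValueError):
    """Malformed record in a genotype or metadata file."""


class DataError(ValueError):
    """Inconsistent content in an otherwise well-formed file."""


@dataclass
class Variant:
    """A biallelic (or flagged multiallelic) SNP with physical and genetic position."""

    id: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    pos_cM: float | None = None
    extra_alts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise DataError(f"variant {self.id}: pos_bp must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"variant {self.id}: ref == alt ({self.ref_allele})")
        if self.pos_cM is None:
            self.pos_cM = self.pos_bp / 1e6  # 1 cM/Mb default

    @property
    def is_multiallelic(self) -> bool:
        return len(self.extra_alts) > 0

    @property
    def is_palindromic(self) -> bool:
        pair = {self.ref_allele.upper(), self.alt_allele.upper()}
        return pair in ({"A", "T"}, {"C", "G"})


def age_group_of(age_years: int) -> str:
    """Map integer age in years to the survey's age bands (12-20 / 20-60 / 60+)."""
    if age_years < 20:
        return "adolescent"
    if age_years < 60:
        return "adult"
    return "older_adult"


@dataclass
class GenotypeMatrix:
    """Diploid alt-dosage calls for N samples x M variants.

    ``calls`` is an (N, M) integer array in {0, 1, 2, MISSING}.  When present,
    ``phased_haplotypes`` is (N, 2, M) in {0, 1, MISSING} and its haplotype
    sums must equal ``calls`` wherever the call is non-missing.
    """

    samples: list[str]
    variants: list[Variant]
    calls: np.ndarray
    phased_haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.variants):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != n:
            raise DataError("duplicate sample ids")
        if len({v.id for v in self.variants}) != m:
            raise DataError("duplicate variant ids")
        if self.phased_haplotypes is not None:
            h = np.asarray(self.phased_haplotypes, dtype=np.int8)
            if h.shape != (n, 2, m):
                raise DataError("phased_haplotypes must have shape (N, 2, M)")
            s = np.where((h == MISSING).any(axis=1), MISSING, h.sum(axis=1))
            ok = (self.calls == MISSING) | (s == self.calls)
            if not ok.all():
                raise DataError("haplotype sums disagree with diploid calls")
            self.phased_haplotypes = h

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (one row per variant, input order)."""
        return pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos_bp": [v.pos_bp for v in self.variants],
                "pos_cM": [v.pos_cM for v in self.variants],
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "multiallelic": [v.is_multiallelic for v in self.variants],
            }
        )

    def subset_variants(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        """Subset to variants by boolean mask or integer index, preserving order."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        h = None if self.phased_haplotypes is None else self.phased_haplotypes[:, :, idx]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx],
            phased_haplotypes=h,
        )

    def subset_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        """Subset to the given sample ids (join by id, keep requested order)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = [pos[s] for s in keep_ids]
        except KeyError as e:
            raise DataError(f"unknown sample id {e.args[0]!r}") from None
        h = None if self.phased_haplotypes is None else self.phased_haplotypes[idx]
        return GenotypeMatrix(
            samples=list(keep_ids),
            variants=list(self.variants),
            calls=self.calls[idx],
            phased_haplotypes=h,
        )

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if all missing)."""
        c = self.calls.astype(float)
        c[self.calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(c, axis=0) / 2.0


@dataclass
class SampleTable:
    """Per-sample survey metadata backed by a DataFrame.

    Columns: sample_id, household_id, relationship_to_head, age_years,
    age_group, sex, category, category_raw, population_label.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "household_id", "relationship_to_head", "age_years", "sex", "category")

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataError(f"sample table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise DataError("duplicate sample ids in sample table")
        if "category_raw" not in df.columns:
            df["category_raw"] = df["category"]
        if "age_group" not in df.columns:
            df["age_group"] = df["age_years"].map(age_group_of)
        else:
            expect = df["age_years"].map(age_group_of)
            if not (df["age_group"] == expect).all():
                raise DataError("age_group inconsistent with age_years")
        if "population_label" not in df.columns:
            df["population_label"] = pd.NA
        bad = df[(df["age_years"] < 12) | (df["age_years"] > 94)]
        if len(bad):
            warnings.warn(f"{len(bad)} samples with age outside 12-94 (retained)")
        bad_rel = set(df["relationship_to_head"]) - set(RELATIONSHIPS)
        if bad_rel:
            raise DataError(f"unknown relationship_to_head values: {sorted(bad_rel)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = set(gm.samples) - set(self.sample_ids)
        if missing:
            raise DataError(f"{len(missing)} genotyped samples absent from sample table")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str, map_path: str | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.2 subset, GT only) into a :class:`GenotypeMatrix`.

    Phase is preserved only when every genotype in the file is phased ('|').
    Multiallelic records are retained with ``extra_alts`` populated; the
    dosage counts copies of the first ALT allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as e:  # htslib raises bare exceptions
        raise ParseError(f"{path}: cannot open as VCF ({e})") from e
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    all_phased = True
    for rec in vcf:
        alts = list(rec.ALT)
        if not alts:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} has no ALT allele")
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            Variant(
                id=vid,
                chrom=str(rec.CHROM),
                pos_bp=int(rec.POS),
                ref_allele=rec.REF,
                alt_allele=alts[0],
                extra_alts=alts[1:],
            )
        )
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        hap = np.empty((len(samples), 2), dtype=np.int8)
        for j, gt in enumerate(gts):
            if len(gt) != 3:
                raise ParseError(
                    f"{path}: mixed or non-diploid ploidy at {rec.CHROM}:{rec.POS} sample {samples[j]}"
                )
            a0, a1, phased = gt
            if not phased:
                all_phased = False
            h0 = MISSING if a0 < 0 else (1 if a0 == 1 else 0)
            h1 = MISSING if a1 < 0 else (1 if a1 == 1 else 0)
            hap[j] = (h0, h1)
            col[j] = MISSING if (h0 == MISSING or h1 == MISSING) else h0 + h1
        rows.append(col)
        haps.append(hap)
    vcf.close()
    if not rows:
        raise ParseError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1)
    phased = np.stack(haps, axis=2) if all_phased else None
    gm = GenotypeMatrix(samples=samples, variants=variants, calls=calls, phased_haplotypes=phased)
    if map_path is not None:
        apply_genetic_map(gm, map_path)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT only; phase written when stored."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscape\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        sep = "|" if gm.phased_haplotypes is not None else "/"
        for i, v in enumerate(gm.variants):
            alt = ",".join([v.alt_allele] + v.extra_alts)
            fields = [v.chrom, str(v.pos_bp), v.id, v.ref_allele, alt, ".", "PASS", ".", "GT"]
            for j in range(gm.n_samples):
                if gm.phased_haplotypes is not None:
                    h0, h1 = gm.phased_haplotypes[j, :, i]
                    a = "." if h0 == MISSING else str(int(h0))
                    b = "." if h1 == MISSING else str(int(h1))
                    fields.append(f"{a}{sep}{b}")
                else:
                    c = gm.calls[j, i]
                    if c == MISSING:
                        fields.append("./.")
                    else:
                        fields.append(("0/0", "0/1", "1/1")[c])
            fh.write("\t".join(fields) + "\n")


def read_genetic_map(path: str) -> pd.DataFrame:
    """Read a 3-column sidecar genetic map (chrom, pos_bp, cM), tab-separated."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos_bp", "cM"):
        if col not in df.columns:
            raise DataError(f"genetic map missing column {col!r}")
    return df


def apply_genetic_map(gm: GenotypeMatrix, map_path: str) -> None:
    """Interpolate pos_cM for each variant from a sidecar map (in place)."""
    gmap = read_genetic_map(map_path)
    for chrom, sub in gmap.groupby("chrom"):
        sub = sub.sort_values("pos_bp")
        bp = sub["pos_bp"].to_numpy(float)
        cm = sub["cM"].to_numpy(float)
        for v in gm.variants:
            if v.chrom == chrom:
                v.pos_cM = float(np.interp(v.pos_bp, bp, cm))


def write_genetic_map(gm: GenotypeMatrix, path: str) -> None:
    rows = [(v.chrom, v.pos_bp, v.pos_cM) for v in gm.variants]
    pd.DataFrame(rows, columns=["chrom", "pos_bp", "cM"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read PLINK-text .ped/.map into dosages.

    The .map is the extended 6-column variant (chrom, id, cM, bp, ref, alt) so
    dosages can be coded against declared alleles; "0 0" pairs become missing.
    """
    variants: list[Variant] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ParseError(f"{map_path}:{ln}: expected 6 columns (chrom id cM bp ref alt)")
            chrom, vid, cm, bp, ref, alt = parts
            variants.append(
                Variant(id=vid, chrom=chrom, pos_bp=int(bp), pos_cM=float(cm), ref_allele=ref, alt_allele=alt)
            )
    m = len(variants)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(f"{ped_path}:{ln}: expected {6 + 2 * m} columns, got {len(parts)}")
            samples.append(parts[1])
            col = np.empty(m, dtype=np.int8)
            for i, v in enumerate(variants):
                a, b = parts[6 + 2 * i], parts[7 + 2 * i]
                col[i] = _pair_to_dosage(a, b, v, f"{ped_path}:{ln}")
            rows.append(col)
    return GenotypeMatrix(samples=samples, variants=variants, calls=np.stack(rows, axis=0))


def _pair_to_dosage(a: str, b: str, v: Variant, where: str) -> int:
    if a == "0" and b == "0":
        return MISSING
    d = 0
    for al in (a, b):
        if al == v.alt_allele:
            d += 1
        elif al != v.ref_allele:
            raise DataError(f"{where}: allele {al!r} not in declared {v.ref_allele}/{v.alt_allele} for {v.id}")
    return d


def write_plink_text(gm: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    with open(map_path, "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t{v.pos_cM:.6f}\t{v.pos_bp}\t{v.ref_allele}\t{v.alt_allele}\n")
    with open(ped_path, "w") as fh:
        for j, sid in enumerate(gm.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for i, v in enumerate(gm.variants):
                c = gm.calls[j, i]
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [v.ref_allele] * (2 - c) + [v.alt_allele] * c
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata and result tables


def _normalize_category(raw: str) -> str:
    """Map a raw category string to a census label, write-in, or NotAnswered.

    Census labels pass through in English or Portuguese; anything else is kept
    verbatim and tagged as a write-in for downstream recoding.
    """
    s = str(raw).strip() if raw is not None and not pd.isna(raw) else ""
    if s == "":
        return NOT_ANSWERED
    if s in CENSUS_CATEGORIES or s == NOT_ANSWERED:
        return s
    import unicodedata

    folded = unicodedata.normalize("NFKD", s.lower())
    folded = "".join(ch for ch in folded if not unicodedata.combining(ch))
    if folded in PT_CENSUS:
        return PT_CENSUS[folded]
    return WRITE_IN


def read_sample_table(tsv_path: str) -> SampleTable:
    """Read the per-sample metadata TSV; write-in categories kept verbatim."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str, "household_id": str})
    for col in ("sample_id", "household_id", "relationship_to_head", "age_years", "sex", "category"):
        if col not in df.columns:
            raise DataError(f"{tsv_path}: missing required column {col!r}")
    raw = df["category"].copy()
    df["category_raw"] = raw.fillna("")
    df["category"] = [_normalize_category(x) for x in raw]
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write any result table as TSV (the package-wide output convention)."""
    table.to_csv(path, sep="\t", index=False)


def flip_dosage(calls: np.ndarray) -> np.ndarray:
    """Swap ref/alt orientation: d -> 2-d, missing preserved."""
    out = np.where(calls == MISSING, MISSING, 2 - calls)
    return out.astype(np.int8)
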