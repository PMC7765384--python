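"""Domain types and I/O for family-exome variant records.

The in-memory model is deliberately small: a :class:`VariantRecord` is one
normalized biallelic variant (multi-allelic sites are split on read) carrying
per-sample genotype calls and an annotation bundle (gene, transcript, dbSNP id,
consequence, protein change, population allele frequency, five-tier
pathogenicity class).  Coordinates are 1-based GRCh37/hg19 throughout; there is
no liftover support.

Variant identity is always ``(chrom, pos, ref, alt)``.  rsIDs are annotation,
never an identity key: candidate tables in this kind of study routinely contain
variants with only HGVS c. notation and no dbSNP id.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("triosift")

MISSING = "."  # text-file representation of an absent value


class TriosiftError(Exception):
    """Base class for fatal input/validation errors."""


class Consequence(str, enum.Enum):
    """Coding consequence vocabulary used by the class/consequence filter."""

    missense = "missense"
    synonymous = "synonymous"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice_region = "splice_region"
    inframe_indel = "inframe_indel"
    utr = "utr"
    intronic = "intronic"
    other = "other"


class Classification(str, enum.Enum):
    """Five-tier pathogenicity scale (ACMG-style, as used by VarSome)."""

    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    uncertain = "uncertain"
    likely_benign = "likely_benign"
    benign = "benign"


def parse_consequence(text: str | None) -> Consequence | None:
    """Map free text to the consequence vocabulary; unknown terms become ``other``."""
    if text is None or text == MISSING or text == "":
        return None
    try:
        return Consequence(text.strip().lower())
    except ValueError:
        logger.warning("unknown consequence %r mapped to 'other'", text)
        return Consequence.other


def parse_classification(text: str | None) -> Classification | None:
    if text is None or text == MISSING or text == "":
        return None
    try:
        return Classification(text.strip().lower())
    except ValueError:
        raise TriosiftError(
            f"classification {text!r} is not in the 5-tier vocabulary "
            f"{[c.value for c in Classification]}"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one biallelic site.

    ``alleles`` is an ordered pair of allele indices (0 = ref, 1 = alt) or
    ``None`` when the genotype is missing (./.).  ``depth`` is the read depth
    (DP) or ``None`` when no depth assertion is made.
    """

    sample_id: str
    alleles: tuple[int, int] | None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if not all(a in (0, 1) for a in self.alleles):
                raise TriosiftError(
                    f"allele indices must be 0/1 after decomposition, got {self.alleles}"
                )
        if self.depth is not None and self.depth < 0:
            raise TriosiftError(f"negative depth {self.depth}")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def has_alt(self) -> bool:
        """True when the call asserts at least one alt allele."""
        return self.alleles is not None and 1 in self.alleles

    @property
    def zygosity(self) -> str:
        if self.alleles is None:
            return "./."
        n = sum(self.alleles)
        return {0: "Ref", 1: "Het", 2: "Hom"}[n]


@dataclass(frozen=True)
class AnnotationBundle:
    """Annotation attached to one variant; every field may be missing."""

    gene_symbol: str | None = None
    transcript_id: str | None = None
    rsid: str | None = None
    consequence: Consequence | None = None
    protein_change: str | None = None
    pop_af: float | None = None
    classification: Classification | None = None
    gene_full_name: str | None = None

    def __post_init__(self) -> None:
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise TriosiftError(f"pop_af must lie in [0, 1], got {self.pop_af}")


VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant with per-sample calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: Mapping[str, GenotypeCall]
    annotation: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise TriosiftError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Numeric-then-lexicographic chromosome ordering (1..22, X, Y, MT, rest)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def record_sort_key(rec: VariantRecord) -> tuple:
    return (*chrom_sort_key(rec.chrom), rec.pos, rec.ref, rec.alt)


@dataclass(frozen=True)
class VariantSet:
    """An ordered, key-unique collection of variants over a fixed sample list.

    Construct through :meth:`from_records`, which sorts and validates.
    """

    records: tuple[VariantRecord, ...]
    sample_ids: tuple[str, ...]

    @classmethod
    def from_records(
        cls, records: Iterable[VariantRecord], sample_ids: Sequence[str]
    ) -> "VariantSet":
        recs = sorted(records, key=record_sort_key)
        sample_ids = tuple(sample_ids)
        seen: set[VariantKey] = set()
        for r in recs:
            if r.key in seen:
                raise TriosiftError(f"duplicate variant key {r.key}")
            seen.add(r.key)
            if set(r.calls) != set(sample_ids):
                raise TriosiftError(
                    f"record {r.key} calls cover {sorted(r.calls)}, "
                    f"expected samples {sorted(sample_ids)}"
                )
        return cls(records=tuple(recs), sample_ids=sample_ids)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    @property
    def keys(self) -> tuple[VariantKey, ...]:
        return tuple(r.key for r in self.records)

    def subset(self, keys: Iterable[VariantKey]) -> "VariantSet":
        wanted = set(keys)
        return VariantSet.from_records(
            (r for r in self.records if r.key in wanted), self.sample_ids
        )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfoKeys:
    """Configurable INFO key names used when annotations travel inside the VCF."""

    pop_af: str = "GNOMAD_AF"
    gene: str = "GENE"
    consequence: str = "CSQ_CLASS"
    classification: str = "ACMG"
    transcript: str = "TRANSCRIPT"
    protein_change: str = "PROTEIN_CHANGE"


def _info_scalar(info, key: str):
    if key not in info:
        return None
    val = info[key]
    if isinstance(val, tuple):
        val = val[0] if val else None
    return val


def read_multisample_vcf(
    path: str | Path,
    wanted_samples: Sequence[str],
    info_keys: InfoKeys | None = None,
) -> VariantSet:
    """Read a multi-sample VCF into a :class:`VariantSet`.

    Multi-allelic sites are split into one record per alt allele with genotype
    indices remapped (the selected alt becomes 1, every other allele 0); this
    naive split performs no left-realignment.  Annotation fields are populated
    from INFO keys when present, else left missing.  Non-SNV records are
    retained (``is_snv`` is False); the consequence filter governs them.
    """
    info_keys = info_keys or InfoKeys()
    path = Path(path)
    vf = pysam.VariantFile(str(path))
    header_samples = list(vf.header.samples)
    for s in wanted_samples:
        if s not in header_samples:
            raise TriosiftError(
                f"sample {s!r} not in VCF header (has {header_samples})"
            )
    records: list[VariantRecord] = []
    for idx, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        for alt_i, alt in enumerate(alts, start=1):
            calls: dict[str, GenotypeCall] = {}
            for s in wanted_samples:
                sample = rec.samples[s]
                try:
                    gt = sample.get("GT", (None,))
                except Exception as exc:  # malformed genotype field
                    raise TriosiftError(
                        f"malformed GT for sample {s} at record {idx} "
                        f"({rec.chrom}:{rec.pos})"
                    ) from exc
                if gt is None or all(a is None for a in gt):
                    alleles = None
                else:
                    remapped = tuple(
                        0 if (a is None or a != alt_i) else 1 for a in gt
                    )
                    if len(remapped) == 1:  # haploid call; duplicate to a pair
                        remapped = (remapped[0], remapped[0])
                    alleles = (remapped[0], remapped[1])
                dp = sample.get("DP", None)
                calls[s] = GenotypeCall(sample_id=s, alleles=alleles, depth=dp)
            ann = AnnotationBundle(
                gene_symbol=_info_scalar(rec.info, info_keys.gene),
                transcript_id=_info_scalar(rec.info, info_keys.transcript),
                rsid=rec.id,
                consequence=parse_consequence(
                    _info_scalar(rec.info, info_keys.consequence)
                ),
                protein_change=_info_scalar(rec.info, info_keys.protein_change),
                pop_af=_maybe_float(_info_scalar(rec.info, info_keys.pop_af)),
                classification=parse_classification(
                    _info_scalar(rec.info, info_keys.classification)
                ),
            )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    calls=calls,
                    annotation=ann,
                )
            )
    vf.close()
    return VariantSet.from_records(records, list(wanted_samples))


def _maybe_float(val) -> float | None:
    if val is None:
        return None
    return float(val)


# ---------------------------------------------------------------------------
# Sidecar annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "rsid",
    "consequence", "protein_change", "pop_af", "classification",
]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the sidecar annotation TSV (``.`` and empty cells are missing)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, na_values=[MISSING, ""],
        keep_default_na=True,
    )
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TriosiftError(f"annotation table lacks columns {missing_cols}")
    return df


def attach_annotations(vset: VariantSet, table: pd.DataFrame) -> VariantSet:
    """Join a sidecar annotation table onto a variant set.

    The join is exact on ``(chrom, pos, ref, alt)``, never on rsid.  Non-missing
    sidecar values replace record values (with a warning when both sides are
    non-missing and disagree); missing sidecar cells leave the record untouched.
    A table row matching no record raises a warning and is dropped.
    """
    keyed: dict[VariantKey, dict] = {}
    for row in table.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in keyed:
            raise TriosiftError(f"duplicate annotation key {key}")
        keyed[key] = row

    def cell(row: dict, name: str):
        v = row.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        return v

    out: list[VariantRecord] = []
    matched: set[VariantKey] = set()
    for rec in vset:
        row = keyed.get(rec.key)
        if row is None:
            out.append(rec)
            continue
        matched.add(rec.key)
        ann = rec.annotation
        updates = dict(
            gene_symbol=cell(row, "gene"),
            transcript_id=cell(row, "transcript"),
            rsid=cell(row, "rsid"),
            consequence=parse_consequence(cell(row, "consequence")),
            protein_change=cell(row, "protein_change"),
            pop_af=_maybe_float(cell(row, "pop_af")),
            classification=parse_classification(cell(row, "classification")),
            gene_full_name=cell(row, "full_name"),
        )
        merged = {}
        for name, new in updates.items():
            old = getattr(ann, name)
            if new is None:
                merged[name] = old
            else:
                if old is not None and old != new:
                    logger.warning(
                        "annotation conflict at %s field %s: %r -> %r (sidecar wins)",
                        rec.key, name, old, new,
                    )
                merged[name] = new
        out.append(replace(rec, annotation=AnnotationBundle(**merged)))
    unmatched = set(keyed) - matched
    for key in sorted(unmatched):
        logger.warning("annotation row %s matches no variant record", key)
    return VariantSet.from_records(out, vset.sample_ids)


# ---------------------------------------------------------------------------
# Candidate table writing
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS_FIXED = [
    "gene", "full_name", "rsid", "chrom", "pos", "transcript", "effect",
]


def format_effect(rec: VariantRecord) -> str:
    ann = rec.annotation
    cons = ann.consequence.value if ann.consequence else MISSING
    if ann.protein_change:
        return f"{cons} ({ann.protein_change})"
    return cons


def write_candidate_table(
    vset: VariantSet,
    path: str | Path,
    affected_samples: Sequence[str] | None = None,
) -> int:
    """Write the candidate variant TSV; returns the number of data rows.

    One zygosity column per affected sample (all samples when no affected list
    is given), in :class:`VariantSet` order.
    """
    affected = list(affected_samples) if affected_samples is not None else list(vset.sample_ids)
    zyg_cols = [f"zygosity_{s}" for s in affected]
    rows = []
    for rec in vset:
        ann = rec.annotation
        row = {
            "gene": ann.gene_symbol or MISSING,
            "full_name": ann.gene_full_name or MISSING,
            "rsid": ann.rsid or MISSING,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "transcript": ann.transcript_id or MISSING,
            "effect": format_effect(rec),
        }
        for s, col in zip(affected, zyg_cols):
            row[col] = rec.calls[s].zygosity
        rows.append(row)
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS_FIXED + zyg_cols)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise TriosiftError(f"cannot write candidate table to {path}: {exc}") from exc
    return len(df)
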