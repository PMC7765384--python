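"""Synthetic family VCFs with known ground truth, and the study fixture.

Two producers:

* :func:`generate_family_vcf` draws an exome-like set of biallelic SNVs over a
  configurable family (default: two affected siblings, one unaffected parent).
  A configurable number of *planted* candidates satisfy all five cascade
  predicates; every *distractor* violates exactly one predicate and passes the
  rest, so the cascade must recover the planted set exactly and assign each
  distractor its designed failure stage (:class:`TruthTable`).

* :func:`build_table3_fixture` reconstructs the published candidate table of
  the family study (27 missense variants over 25 genes: one gene contributes
  three adjacent SNVs) as a trio VCF + sidecar annotations + PED, padded with
  distractors (six common benign APOH variants shared by the siblings, three
  common thrombophilia-gene polymorphisms carried by all three members, and
  three father-carried rare missense variants) so a cascade run on it genuinely
  filters.  Allele frequencies (1e-4), classifications (uncertain) and depths
  (100x) of the reconstructed candidates are synthetic fixture metadata — the
  published table prints none of them — chosen safely inside the passing
  region of every filter.

Everything is deterministic given the seed: one seeded generator, and emitted
records are sorted by genome coordinate (never generation order), so
byte-identical output survives internal refactors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import (
    STAGE_CLASS,
    STAGE_DEPTH,
    STAGE_FREQUENCY,
    STAGE_SHARING,
    STAGE_UNAFFECTED,
)
from .variant_model import MISSING, TriosiftError, VariantKey, chrom_sort_key

logger = logging.getLogger("triosift")

DISTRACTOR_CLASSES = (
    "common_af",
    "not_shared",
    "unaffected_carrier",
    "benign_class",
    "silent_consequence",
    "low_depth",
)

#: which cascade stage each distractor class is designed to fail
CLASS_TO_STAGE = {
    "common_af": STAGE_FREQUENCY,
    "not_shared": STAGE_SHARING,
    "unaffected_carrier": STAGE_UNAFFECTED,
    "benign_class": STAGE_CLASS,
    "silent_consequence": STAGE_CLASS,
    "low_depth": STAGE_DEPTH,
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic family-exome run.

    The allele-frequency spectrum is split around the 1% rare-variant cut-off:
    planted candidates draw from ``rare_af_range`` (log-uniform) or carry no
    AF at all, common distractors from ``common_af_range`` (uniform).  Depths
    are Gaussian around ``depth_mean`` with a hard ``depth_floor`` so that
    only the low-depth distractor class can dip below the 20x threshold
    (``low_depth_below``).
    """

    n_affected: int = 2
    n_unaffected: int = 1
    n_planted: int = 5
    n_distractors_per_class: int = 5
    distractor_classes: tuple[str, ...] = DISTRACTOR_CLASSES
    rare_af_range: tuple[float, float] = (1e-5, 5e-3)
    common_af_range: tuple[float, float] = (0.05, 0.5)
    depth_mean: float = 100.0
    depth_floor: int = 30
    low_depth_below: int = 20
    missing_af_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_affected, self.n_unaffected, self.n_planted,
               self.n_distractors_per_class) < 0 or self.n_affected == 0:
            raise TriosiftError("counts must be >= 0 (and n_affected >= 1)")
        unknown = set(self.distractor_classes) - set(DISTRACTOR_CLASSES)
        if unknown:
            raise TriosiftError(f"unknown distractor class(es) {sorted(unknown)}")
        if not (0 < self.rare_af_range[0] <= self.rare_af_range[1] < 0.01):
            raise TriosiftError("rare_af_range must lie entirely below 0.01")
        if not (0.01 < self.common_af_range[0] <= self.common_af_range[1] <= 1):
            raise TriosiftError("common_af_range must lie entirely above 0.01")
        if self.depth_floor < self.low_depth_below:
            raise TriosiftError("depth_floor must be >= low_depth_below")
        if (
            "unaffected_carrier" in self.distractor_classes
            and self.n_distractors_per_class > 0
            and self.n_unaffected == 0
        ):
            raise TriosiftError(
                "unaffected_carrier distractors need at least one unaffected sample"
            )

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(f"AFF{i+1}" for i in range(self.n_affected))

    @property
    def unaffected_ids(self) -> tuple[str, ...]:
        return tuple(f"UNAFF{i+1}" for i in range(self.n_unaffected))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.affected_ids + self.unaffected_ids


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one generated dataset."""

    planted: frozenset[VariantKey]
    distractors: dict[VariantKey, str]  # key -> designed failure stage

    def __post_init__(self) -> None:
        overlap = self.planted & set(self.distractors)
        if overlap:
            raise TriosiftError(f"planted/distractor overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class GeneratedFamily:
    vcf: Path
    annotations: Path
    ped: Path
    truth: TruthTable


# ---------------------------------------------------------------------------
# Low-level emitters (fixed dialects, byte-deterministic)
# ---------------------------------------------------------------------------

def _fmt_af(af: float | None) -> str:
    return MISSING if af is None else format(af, ".6g")


def _write_vcf(rows: list[dict], sample_ids: tuple[str, ...], path: Path) -> None:
    """Write a minimal VCF v4.2 (GT:DP) from pre-sorted row dicts."""
    contigs = sorted({r["chrom"] for r in rows}, key=chrom_sort_key)
    lines = ["##fileformat=VCFv4.2", "##source=triosift-synthetic"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    for r in rows:
        gts = "\t".join(f"{r['gt'][s]}:{r['dp'][s]}" for s in sample_ids)
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t{r['rsid'] or MISSING}\t{r['ref']}\t{r['alt']}"
            f"\t.\tPASS\t.\tGT:DP\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_annotations(rows: list[dict], path: Path) -> None:
    header = [
        "chrom", "pos", "ref", "alt", "gene", "transcript", "rsid",
        "consequence", "protein_change", "pop_af", "classification", "full_name",
    ]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join([
            r["chrom"], str(r["pos"]), r["ref"], r["alt"],
            r["gene"] or MISSING, r["transcript"] or MISSING, r["rsid"] or MISSING,
            r["consequence"] or MISSING, r["protein_change"] or MISSING,
            _fmt_af(r["pop_af"]), r["classification"] or MISSING,
            r.get("full_name") or MISSING,
        ]))
    path.write_text("\n".join(lines) + "\n")


def _write_ped(cfg_affected: tuple[str, ...], cfg_unaffected: tuple[str, ...], path: Path) -> None:
    father = cfg_unaffected[0] if cfg_unaffected else "0"
    lines = []
    for i, sid in enumerate(cfg_affected):
        sex = "2" if i % 2 == 0 else "1"
        lines.append(f"FAM1\t{sid}\t{father}\t0\t{sex}\t2")
    for sid in cfg_unaffected:
        lines.append(f"FAM1\t{sid}\t0\t0\t1\t1")
    path.write_text("\n".join(lines) + "\n")


def _sort_rows(rows: list[dict]) -> list[dict]:
    return sorted(rows, key=lambda r: (*chrom_sort_key(r["chrom"]), r["pos"], r["ref"], r["alt"]))


# ---------------------------------------------------------------------------
# Random family generator
# ---------------------------------------------------------------------------

def generate_family_vcf(cfg: SimulationConfig, out_dir: str | Path) -> GeneratedFamily:
    """Generate VCF + annotation TSV + PED + truth table under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids

    n_total = cfg.n_planted + len(cfg.distractor_classes) * cfg.n_distractors_per_class
    # unique loci on autosome-named synthetic contigs
    taken: set[tuple[str, int]] = set()
    loci: list[tuple[str, int]] = []
    while len(loci) < n_total:
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1_000_000, 50_000_000))
        if (chrom, pos) not in taken:
            taken.add((chrom, pos))
            loci.append((chrom, pos))

    def draw_depths() -> dict[str, int]:
        return {
            s: max(cfg.depth_floor, int(round(rng.normal(cfg.depth_mean, cfg.depth_mean / 5))))
            for s in samples
        }

    def base_row(i: int, chrom: str, pos: int) -> dict:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        af = None if rng.random() < cfg.missing_af_fraction else float(
            np.exp(rng.uniform(np.log(cfg.rare_af_range[0]), np.log(cfg.rare_af_range[1])))
        )
        cls = str(rng.choice(
            ["uncertain", "likely_pathogenic", "pathogenic"], p=[0.7, 0.2, 0.1]
        ))
        rsid = f"rs9{int(rng.integers(0, 10_000_000)):07d}" if rng.random() < 0.5 else None
        gt = {s: "0/1" for s in cfg.affected_ids}
        gt.update({s: "0/0" for s in cfg.unaffected_ids})
        return {
            "chrom": chrom, "pos": pos, "ref": str(ref), "alt": str(alt),
            "rsid": rsid, "gene": f"GENE{i:04d}", "transcript": f"NM_{900000+i}.1",
            "consequence": "missense", "protein_change": f"p.Ala{100+i}Val",
            "pop_af": af, "classification": cls, "gt": gt, "dp": draw_depths(),
        }

    rows: list[dict] = []
    planted: set[VariantKey] = set()
    distractors: dict[VariantKey, str] = {}
    slot = 0
    for _ in range(cfg.n_planted):
        chrom, pos = loci[slot]
        row = base_row(slot, chrom, pos)
        rows.append(row)
        planted.add((chrom, pos, row["ref"], row["alt"]))
        slot += 1
    for klass in cfg.distractor_classes:
        for _ in range(cfg.n_distractors_per_class):
            chrom, pos = loci[slot]
            row = base_row(slot, chrom, pos)
            if klass == "common_af":
                row["pop_af"] = float(rng.uniform(*cfg.common_af_range))
            elif klass == "not_shared":
                victim = str(rng.choice(cfg.affected_ids))
                row["gt"][victim] = "0/0"
            elif klass == "unaffected_carrier":
                carrier = str(rng.choice(cfg.unaffected_ids))
                row["gt"][carrier] = "0/1"
            elif klass == "benign_class":
                row["classification"] = str(rng.choice(["benign", "likely_benign"]))
            elif klass == "silent_consequence":
                row["consequence"] = str(rng.choice(["synonymous", "utr", "intronic"]))
            elif klass == "low_depth":
                victim = str(rng.choice(samples))
                row["dp"][victim] = int(rng.integers(1, cfg.low_depth_below))
            rows.append(row)
            distractors[(chrom, pos, row["ref"], row["alt"])] = CLASS_TO_STAGE[klass]
            slot += 1

    rows = _sort_rows(rows)
    vcf = out_dir / "family.vcf"
    ann = out_dir / "annotations.tsv"
    ped = out_dir / "family.ped"
    _write_vcf(rows, samples, vcf)
    _write_annotations(rows, ann)
    _write_ped(cfg.affected_ids, cfg.unaffected_ids, ped)
    truth = TruthTable(planted=frozenset(planted), distractors=distractors)
    _write_truth(truth, out_dir / "truth.tsv")
    return GeneratedFamily(vcf=vcf, annotations=ann, ped=ped, truth=truth)


def _write_truth(truth: TruthTable, path: Path) -> None:
    lines = ["chrom\tpos\tref\talt\trole"]
    entries = [(k, "planted") for k in truth.planted] + [
        (k, f"distractor:{s}") for k, s in truth.distractors.items()
    ]
    for key, role in sorted(entries, key=lambda e: (*chrom_sort_key(e[0][0]), e[0][1], e[0][2], e[0][3])):
        lines.append(f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{role}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Study fixture
# ---------------------------------------------------------------------------

FIXTURE_AFFECTED = ("PT1", "PT2")
FIXTURE_UNAFFECTED = ("FATHER",)
FIXTURE_SAMPLES = FIXTURE_AFFECTED + FIXTURE_UNAFFECTED

#: synthetic metadata for the reconstructed candidate rows (not published data)
FIXTURE_CANDIDATE_AF = 1e-4
FIXTURE_DEPTH = 100

# distractors: six common benign APOH (beta-2-glycoprotein I) variants shared
# by the siblings; positions deliberately avoid the catalogued APOH missense
# coordinate so known-variant matching stays a true negative
_APOH_DISTRACTORS = [
    # pos, ref, alt, consequence, af
    (64208101, "A", "G", "missense", 0.12),
    (64208215, "C", "T", "synonymous", 0.45),
    (64208330, "G", "A", "missense", 0.23),
    (64208444, "T", "C", "utr", 0.08),
    (64208557, "C", "G", "missense", 0.31),
    (64208663, "G", "T", "synonymous", 0.19),
]

# common thrombophilia-gene polymorphisms carried by all three family members
_THROMBO_DISTRACTORS = [
    # gene, chrom, pos, ref, alt, consequence, af
    ("MTHFR", "1", 11854800, "G", "A", "missense", 0.30),
    ("F13A1", "6", 6320100, "T", "C", "missense", 0.25),
    ("FGB", "4", 155486200, "C", "T", "synonymous", 0.40),
]

# rare missense variants also carried by the father (fail unaffected exclusion)
_FATHER_DISTRACTORS = [
    ("TTN", "2", 179420000, "C", "T"),
    ("OBSCN", "1", 228410000, "G", "A"),
    ("AHNAK2", "14", 105410000, "A", "G"),
]


def load_candidate_transcription() -> pd.DataFrame:
    """The packaged transcription of the study's candidate-variant table."""
    src = resources.files("triosift.data").joinpath("candidate_variants.tsv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str}, na_values=[MISSING])


def build_table3_fixture(out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the fixture trio (VCF, annotation TSV, PED) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []

    def gt(pt1: str, pt2: str, father: str) -> dict[str, str]:
        return {"PT1": pt1, "PT2": pt2, "FATHER": father}

    dp_all = {s: FIXTURE_DEPTH for s in FIXTURE_SAMPLES}

    for row in load_candidate_transcription().to_dict("records"):
        rows.append({
            "chrom": str(row["chrom"]), "pos": int(row["pos"]),
            "ref": row["ref"], "alt": row["alt"],
            "rsid": None if pd.isna(row["rsid"]) else row["rsid"],
            "gene": row["gene"], "transcript": row["transcript"],
            "consequence": "missense", "protein_change": row["protein_change"],
            "pop_af": FIXTURE_CANDIDATE_AF, "classification": "uncertain",
            "full_name": row["full_name"],
            "gt": gt("0/1", "0/1", "0/0"), "dp": dict(dp_all),
        })
    for i, (pos, ref, alt, cons, af) in enumerate(_APOH_DISTRACTORS):
        rows.append({
            "chrom": "17", "pos": pos, "ref": ref, "alt": alt,
            "rsid": None, "gene": "APOH", "transcript": "NM_000042.3",
            "consequence": cons, "protein_change": None,
            "pop_af": af, "classification": "benign",
            "full_name": "Apolipoprotein H (beta-2-glycoprotein I)",
            "gt": gt("0/1", "0/1", "0/1"), "dp": dict(dp_all),
        })
    for gene, chrom, pos, ref, alt, cons, af in _THROMBO_DISTRACTORS:
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "rsid": None, "gene": gene, "transcript": None,
            "consequence": cons, "protein_change": None,
            "pop_af": af, "classification": "benign", "full_name": None,
            "gt": gt("0/1", "0/1", "0/1"), "dp": dict(dp_all),
        })
    for gene, chrom, pos, ref, alt in _FATHER_DISTRACTORS:
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "rsid": None, "gene": gene, "transcript": None,
            "consequence": "missense", "protein_change": None,
            "pop_af": FIXTURE_CANDIDATE_AF, "classification": "uncertain",
            "full_name": None,
            "gt": gt("0/1", "0/1", "0/1"), "dp": dict(dp_all),
        })

    rows = _sort_rows(rows)
    vcf = out_dir / "family_study.vcf"
    ann = out_dir / "family_study_annotations.tsv"
    ped = out_dir / "family_study.ped"
    _write_vcf(rows, FIXTURE_SAMPLES, vcf)
    _write_annotations(rows, ann)
    _write_ped(FIXTURE_AFFECTED, FIXTURE_UNAFFECTED, ped)
    return vcf, ann, ped
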