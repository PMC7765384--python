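"""Family design: affected/unaffected sample partition from a PED file.

The study design this package targets is two affected siblings and one
unaffected parent, but nothing here assumes a fixed trio shape: any number of
affected samples (at least one) and any number of unaffected controls
(including zero — e.g. a deceased, ungenotyped parent is simply absent) work
with the downstream segregation filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .variant_model import TriosiftError, VariantSet

logger = logging.getLogger("triosift")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    affected: bool
    role: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise TriosiftError("empty sample_id in family design")


@dataclass(frozen=True)
class FamilyDesign:
    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise TriosiftError(f"duplicate sample id(s) in family design: {sorted(dupes)}")

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.affected)

    @property
    def unaffected_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if not s.affected)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)


def read_ped(path: str | Path) -> FamilyDesign:
    """Read a standard 6-column PED file (FID IID PAT MAT SEX PHENO).

    Phenotype 2 means affected, 1 unaffected; 0 or -9 (unknown) excludes the
    sample with a warning.  Output is insensitive to line order: samples are
    kept in file order but the affected/unaffected partition depends only on
    the phenotype column.
    """
    samples: list[SampleInfo] = []
    seen: set[str] = set()
    lines = Path(path).read_text().splitlines()
    data_lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not data_lines:
        raise TriosiftError(f"PED file {path} has no data lines")
    for lineno, ln in enumerate(data_lines, start=1):
        cols = ln.split()
        if len(cols) < 6:
            raise TriosiftError(
                f"PED line {lineno} has {len(cols)} columns, expected >= 6"
            )
        _fid, iid, pat, mat, _sex, pheno = cols[:6]
        if iid in seen:
            raise TriosiftError(f"duplicate sample id {iid!r} in PED file")
        seen.add(iid)
        if pheno == "2":
            affected = True
        elif pheno == "1":
            affected = False
        else:
            logger.warning(
                "sample %s has unknown phenotype %r; excluded from design", iid, pheno
            )
            continue
        role = "child" if (pat != "0" or mat != "0") else "founder"
        samples.append(SampleInfo(sample_id=iid, affected=affected, role=role))
    return FamilyDesign(samples=tuple(samples))


def validate_design(design: FamilyDesign, vset: VariantSet) -> FamilyDesign:
    """Check the design against a variant set; returns the design unchanged.

    Fatal when a design sample is absent from the VCF sample list or when no
    affected sample exists (the sharing filter would be vacuous).
    """
    missing = [s for s in design.sample_ids if s not in vset.sample_ids]
    problems = []
    if missing:
        problems.append(f"design sample(s) {missing} absent from variant set samples "
                        f"{list(vset.sample_ids)}")
    if not design.affected_ids:
        problems.append("family design has no affected sample")
    if problems:
        raise TriosiftError("invalid family design: " + "; ".join(problems))
    return design
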