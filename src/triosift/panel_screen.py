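"""Gene-panel and known-variant screens.

Three curated resources ship with the package (plain TSV under
``triosift/data``):

* ``gene_panels.tsv`` — the 8-gene thrombophilia panel, the 16-gene
  thrombotic-PAPS association panel, and the 7 genes-of-interest from the
  family study this package reconstructs;
* ``known_variants_aps.tsv`` — the catalogue of variants previously associated
  with antiphospholipid syndrome (rsID-anchored where one exists; haplotype
  entries are gene-level only);
* ``gene_aliases.tsv`` — legacy-name to HGNC mapping (B2GP1→APOH, GP Ia→ITGA2,
  GP IIIa→ITGB3, ZPI→SERPINA10), because the clinical literature mixes both.

Matching against the known-variant catalogue treats rsIDs as authoritative
when present on both sides; coordinates are used only when the catalogue entry
has no rsID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .variant_model import (
    MISSING,
    TriosiftError,
    VariantRecord,
    VariantSet,
)

logger = logging.getLogger("triosift")


def _data_path(name: str):
    return resources.files("triosift.data").joinpath(name)


def _norm(symbol: str) -> str:
    """Normalize a gene symbol for lookup (case- and space-insensitive)."""
    return symbol.strip().upper().replace(" ", "")


def load_gene_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Load the alias→canonical map; fatal on an alias bound to two symbols."""
    src = Path(path) if path is not None else _data_path("gene_aliases.tsv")
    df = pd.read_csv(src, sep="\t")
    aliases: dict[str, str] = {}
    for row in df.itertuples(index=False):
        key = _norm(row.alias)
        canon = str(row.canonical).strip()
        if key in aliases and aliases[key] != canon:
            raise TriosiftError(
                f"alias {row.alias!r} resolves to both {aliases[key]!r} and {canon!r}"
            )
        aliases[key] = canon
    return aliases


def canonical_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Resolve a (possibly legacy) gene symbol to its canonical HGNC symbol."""
    if aliases is None:
        aliases = load_gene_aliases()
    return aliases.get(_norm(symbol), symbol.strip())


@dataclass(frozen=True)
class GenePanel:
    """A named set of canonical HGNC gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise TriosiftError(f"panel {self.name!r} contains an empty gene symbol")

    def union(self, other: "GenePanel") -> "GenePanel":
        return GenePanel(name=f"{self.name}+{other.name}", genes=self.genes | other.genes)


def available_panels(path: str | Path | None = None) -> list[str]:
    src = Path(path) if path is not None else _data_path("gene_panels.tsv")
    df = pd.read_csv(src, sep="\t")
    return sorted(df["panel_name"].unique())


def load_panel(
    name: str,
    path: str | Path | None = None,
    aliases: dict[str, str] | None = None,
) -> GenePanel:
    """Load one named panel, resolving legacy symbols to canonical ones."""
    src = Path(path) if path is not None else _data_path("gene_panels.tsv")
    if aliases is None:
        aliases = load_gene_aliases()
    df = pd.read_csv(src, sep="\t")
    sub = df[df["panel_name"] == name]
    if sub.empty:
        raise TriosiftError(
            f"unknown panel {name!r}; available: {sorted(df['panel_name'].unique())}"
        )
    genes = frozenset(canonical_symbol(g, aliases) for g in sub["gene_symbol"])
    return GenePanel(name=name, genes=genes)


@dataclass(frozen=True)
class KnownVariant:
    """One catalogue entry for a variant previously associated with the disease.

    Haplotype-style entries without a printed point coordinate carry neither
    rsid nor pos and are matchable at gene level only.
    """

    gene: str
    rsid: str | None
    chrom: str | None
    pos: int | None
    transcript: str = ""
    effect: str = ""
    reference: str = ""

    @property
    def is_gene_level(self) -> bool:
        return self.rsid is None and self.pos is None


def load_known_variants(path: str | Path | None = None) -> list[KnownVariant]:
    src = Path(path) if path is not None else _data_path("known_variants_aps.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str, na_values=[MISSING, ""])
    aliases = load_gene_aliases()
    out = []
    for row in df.to_dict("records"):
        out.append(
            KnownVariant(
                gene=canonical_symbol(str(row["gene"]), aliases),
                rsid=None if pd.isna(row["rsid"]) else str(row["rsid"]),
                chrom=None if pd.isna(row["chrom"]) else str(row["chrom"]),
                pos=None if pd.isna(row["pos"]) else int(row["pos"]),
                transcript="" if pd.isna(row["transcript"]) else str(row["transcript"]),
                effect="" if pd.isna(row["effect"]) else str(row["effect"]),
                reference="" if pd.isna(row["reference"]) else str(row["reference"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenHit:
    record: VariantRecord
    gene: str
    known: KnownVariant | None = None


@dataclass
class ScreenReport:
    panel_name: str
    hits: list[ScreenHit] = field(default_factory=list)
    n_screened: int = 0

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    def summary(self) -> str:
        lines = [f"panel {self.panel_name}: {self.n_hits} hit(s) / {self.n_screened} variant(s) screened"]
        for h in self.hits:
            ann = h.record.annotation
            af = "." if ann.pop_af is None else f"{ann.pop_af:g}"
            cls = ann.classification.value if ann.classification else "."
            zyg = ",".join(
                f"{s}:{h.record.calls[s].zygosity}" for s in h.record.calls
            )
            extra = f" known={h.known.rsid or h.known.effect}" if h.known else ""
            lines.append(
                f"  {h.gene} {h.record.chrom}:{h.record.pos} {h.record.ref}>{h.record.alt}"
                f" af={af} class={cls} {zyg}{extra}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            ann = h.record.annotation
            rows.append(
                {
                    "panel": self.panel_name,
                    "gene": h.gene,
                    "chrom": h.record.chrom,
                    "pos": h.record.pos,
                    "ref": h.record.ref,
                    "alt": h.record.alt,
                    "rsid": ann.rsid or MISSING,
                    "pop_af": MISSING if ann.pop_af is None else ann.pop_af,
                    "classification": ann.classification.value if ann.classification else MISSING,
                    "known_match": (h.known.rsid or h.known.effect) if h.known else MISSING,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "panel", "gene", "chrom", "pos", "ref", "alt", "rsid",
                "pop_af", "classification", "known_match",
            ],
        )


def screen_panel_genes(vset: VariantSet, panel: GenePanel) -> ScreenReport:
    """Report every variant whose (canonical) gene symbol lies in the panel.

    Zero hits is a valid, explicit result — in the reconstructed study neither
    affected sibling carried a reportable variant in any thrombophilia or
    thrombotic-PAPS panel gene.
    """
    aliases = load_gene_aliases()
    report = ScreenReport(panel_name=panel.name, n_screened=len(vset))
    for rec in vset:
        sym = rec.annotation.gene_symbol
        if sym is None:
            continue
        canon = canonical_symbol(sym, aliases)
        if canon in panel.genes:
            report.hits.append(ScreenHit(record=rec, gene=canon))
    return report


def match_known_variants(
    vset: VariantSet, catalogue: list[KnownVariant]
) -> ScreenReport:
    """Match a variant set against an rsID-anchored known-variant catalogue.

    rsIDs are authoritative when present on both sides: coordinate agreement
    never overrides an rsID mismatch.  Entries without an rsID match on
    (chrom, pos); gene-level-only entries match any variant on the gene.
    """
    aliases = load_gene_aliases()
    report = ScreenReport(panel_name="known_variants", n_screened=len(vset))
    for rec in vset:
        ann = rec.annotation
        for kv in catalogue:
            if kv.rsid is not None:
                if ann.rsid is not None and ann.rsid == kv.rsid:
                    report.hits.append(ScreenHit(record=rec, gene=kv.gene, known=kv))
            elif kv.pos is not None:
                if rec.chrom == kv.chrom and rec.pos == kv.pos:
                    report.hits.append(ScreenHit(record=rec, gene=kv.gene, known=kv))
            else:  # gene-level-only (haplotype) entry
                sym = ann.gene_symbol
                if sym is not None and canonical_symbol(sym, aliases) == kv.gene:
                    report.hits.append(ScreenHit(record=rec, gene=kv.gene, known=kv))
    return report


@dataclass(frozen=True)
class GeneReportRow:
    record: VariantRecord
    pop_af: float | None
    classification: str
    common: bool  # population AF at or above the rare-variant cut-off


def gene_level_report(
    vset_all_prefilter: VariantSet,
    gene: str,
    common_af_threshold: float = 0.01,
) -> list[GeneReportRow]:
    """All variants on one gene in the pre-cascade, affected-shared set.

    This deliberately bypasses the cascade so that common/benign variation is
    visible — the use case is a focused look at a biologically central gene
    (in the reconstructed study, beta-2-glycoprotein I / APOH) where the
    interesting answer may be "six shared SNPs, all common, all benign".
    """
    aliases = load_gene_aliases()
    target = canonical_symbol(gene, aliases)
    rows = []
    for rec in vset_all_prefilter:
        sym = rec.annotation.gene_symbol
        if sym is None or canonical_symbol(sym, aliases) != target:
            continue
        af = rec.annotation.pop_af
        cls = rec.annotation.classification
        rows.append(
            GeneReportRow(
                record=rec,
                pop_af=af,
                classification=cls.value if cls else "missing",
                common=(af is not None and af >= common_af_threshold),
            )
        )
    return rows
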