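"""Reading and writing annotated VCF and the tabular artifacts.

VCF reading goes through cyvcf2 (htslib); records are normalized into
the internal model by splitting multi-allelic sites into one
:class:`~gavin.model.AnnotatedVariant` per (record, alt allele, gene)
and taking, per gene, the most severe impact listed in the SnpEff-style
``ANN`` field.  INFO key names are configurable because upstream
annotators vary.  VCF writing serializes the internal model back to
plain-text VCF v4.2 with a minimal single-gene ``ANN`` entry, so that
read → write → read is the identity on all modeled fields.

Coordinates are VCF-style: 1-based, inclusive, preserved verbatim.
Absent allele frequency stays absent at this layer (the calibration maps
absent to 0 explicitly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Optional, Union

import pandas as pd

from .model import (
    AnnotatedVariant,
    CalibrationCategory,
    GeneCalibration,
    Impact,
    ImpactDistribution,
    Judgment,
    Label,
)

__all__ = [
    "InfoFields",
    "VcfParseError",
    "read_annotated_vcf",
    "write_vcf",
    "write_classified_vcf",
    "read_calibration_table",
    "write_calibration_table",
    "read_cgd",
    "read_truth_table",
    "write_truth_table",
]


class VcfParseError(ValueError):
    """A VCF record or header could not be interpreted."""


@dataclass(frozen=True, slots=True)
class InfoFields:
    """Configurable INFO key names for annotated VCFs."""

    ann: str = "ANN"
    cadd: str = "CADD"
    af: str = "EXAC_AF"
    label: str = "CLINSIG"
    judgment: str = "GAVIN"


_ALLELE_CHARS = frozenset("ACGTN")


def _label_from_significance(sig: Optional[str]) -> Optional[Label]:
    """Normalize a free-text clinical significance to a truth label.

    "Likely pathogenic"/"Likely benign" merge into Pathogenic/Benign;
    the pathogenic test is checked first and is a plain substring match.
    """
    if sig is None:
        return None
    s = sig.lower()
    if "pathogenic" in s:
        return Label.PATHOGENIC
    if "benign" in s:
        return Label.BENIGN
    if "uncertain" in s or "vus" in s:
        return Label.VUS
    return None


def _per_alt(value, alt_index: int, n_alts: int):
    """Resolve an INFO value that may be scalar or per-alt (Number=A)."""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if value else None
    return value


def _parse_ann(
    ann: str, record_no: int
) -> list[tuple[str, Optional[str], Optional[Impact]]]:
    """Parse a SnpEff ANN field into (allele, gene, impact) triples."""
    out = []
    for entry in ann.split(","):
        parts = entry.split("|")
        allele = parts[0] if parts else ""
        impact_tok = parts[2].strip() if len(parts) > 2 else ""
        gene = parts[3].strip() if len(parts) > 3 else ""
        impact: Optional[Impact] = None
        if impact_tok:
            try:
                impact = Impact(impact_tok.upper())
            except ValueError:
                raise VcfParseError(
                    f"record {record_no}: unknown impact token {impact_tok!r} in ANN"
                ) from None
        out.append((allele, gene or None, impact))
    return out


def _expand_record(
    rec,
    record_no: int,
    fields: InfoFields,
    on_reject: Optional[Callable[[int, str], None]],
) -> Iterator[AnnotatedVariant]:
    """Expand one VCF record into per-(alt, gene) AnnotatedVariants."""
    alts = rec.ALT or []
    ref = rec.REF or ""
    if not ref or not set(ref.upper()) <= _ALLELE_CHARS:
        if on_reject:
            on_reject(record_no, f"unsupported REF allele {ref!r}")
        return
    ann_raw = rec.INFO.get(fields.ann)
    triples = _parse_ann(str(ann_raw), record_no) if ann_raw is not None else []
    sig_raw = rec.INFO.get(fields.label)
    significance = str(sig_raw) if sig_raw is not None else None
    label = _label_from_significance(significance)
    for ai, alt in enumerate(alts):
        if not alt or not set(alt.upper()) <= _ALLELE_CHARS:
            if on_reject:
                on_reject(record_no, f"unsupported ALT allele {alt!r}")
            continue
        cadd = _per_alt(rec.INFO.get(fields.cadd), ai, len(alts))
        af = _per_alt(rec.INFO.get(fields.af), ai, len(alts))
        cadd = None if cadd is None or (isinstance(cadd, float) and math.isnan(cadd)) else float(cadd)
        af = None if af is None or (isinstance(af, float) and math.isnan(af)) else float(af)
        # most severe impact per gene, for annotations of this allele
        gene_impacts: dict[Optional[str], Optional[Impact]] = {}
        for allele, gene, impact in triples:
            if allele != alt:
                continue
            prev = gene_impacts.get(gene)
            if prev is None or (impact is not None and impact.severity > prev.severity):
                gene_impacts[gene] = impact
        if not gene_impacts:
            gene_impacts = {None: None}
        for gene, impact in sorted(
            gene_impacts.items(), key=lambda kv: (kv[0] is None, kv[0] or "")
        ):
            yield AnnotatedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                gene=gene,
                impact=impact,
                cadd=cadd,
                af=af,
                label=label,
                significance=significance,
            )


def _iter_vcf(path: Union[str, Path]):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF reading") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            yield record_no, rec
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record {record_no + 1}: {exc}") from exc
    finally:
        vcf.close()


def read_annotated_vcf(
    path: Union[str, Path],
    fields: InfoFields = InfoFields(),
    on_reject: Optional[Callable[[int, str], None]] = None,
) -> Iterator[AnnotatedVariant]:
    """Stream AnnotatedVariants from a VCF (plain or bgzipped).

    Yields one variant per (record, alt allele, gene); when the ANN field
    lists several transcripts for a gene, the most severe impact for that
    gene is kept.  Records or alleles that cannot be modeled (symbolic
    alleles, spanning deletions) are reported through ``on_reject`` with
    their 1-based record number and skipped — never silently dropped.
    Missing INFO keys yield absent values, never errors.
    """
    for record_no, rec in _iter_vcf(path):
        yield from _expand_record(rec, record_no, fields, on_reject)


def read_classified_vcf(
    path: Union[str, Path],
    fields: InfoFields = InfoFields(),
    on_reject: Optional[Callable[[int, str], None]] = None,
) -> Iterator[tuple[AnnotatedVariant, Optional["Verdict"]]]:
    """Stream (variant, verdict) pairs from a VCF written by
    :func:`write_classified_vcf` (verdict ``None`` when the judgment INFO
    key is missing)."""
    from .model import Verdict

    for record_no, rec in _iter_vcf(path):
        raw = rec.INFO.get(fields.judgment)
        verdict = None
        if raw is not None:
            verdict = Verdict(str(raw).split("|", 1)[0])
        for v in _expand_record(rec, record_no, fields, on_reject):
            yield v, verdict


def _vcf_header(contigs: list[str], fields: InfoFields, with_judgment: bool) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        f'##INFO=<ID={fields.ann},Number=.,Type=String,Description='
        '"Functional annotations: Allele|Annotation|Impact|Gene_Name">',
        f'##INFO=<ID={fields.cadd},Number=1,Type=Float,Description='
        '"Scaled CADD score">',
        f'##INFO=<ID={fields.af},Number=1,Type=Float,Description='
        '"Population minor allele frequency">',
        f'##INFO=<ID={fields.label},Number=1,Type=String,Description='
        '"Clinical significance">',
    ]
    if with_judgment:
        lines.append(
            f'##INFO=<ID={fields.judgment},Number=1,Type=String,Description='
            '"Classification|Rule|Reason">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def _sanitize(text: str) -> str:
    """Make a free-text string safe inside a VCF INFO value."""
    for bad in (";", "=", ",", " ", "\t", "\n"):
        text = text.replace(bad, "_")
    return text


def _info_string(
    v: AnnotatedVariant, judgment: Optional[Judgment], fields: InfoFields
) -> str:
    parts = []
    if v.gene is not None or v.impact is not None:
        impact = v.impact.value if v.impact is not None else ""
        parts.append(f"{fields.ann}={v.alt}|region_variant|{impact}|{v.gene or ''}|")
    if v.cadd is not None:
        parts.append(f"{fields.cadd}={v.cadd!r}")
    if v.af is not None:
        parts.append(f"{fields.af}={v.af!r}")
    sig = v.significance if v.significance is not None else (
        v.label.value if v.label is not None else None
    )
    if sig is not None:
        parts.append(f"{fields.label}={_sanitize(sig)}")
    if judgment is not None:
        parts.append(
            f"{fields.judgment}={judgment.verdict.value}|{judgment.rule}|"
            f"{_sanitize(judgment.reason)}"
        )
    return ";".join(parts) if parts else "."


def _write(
    items: Iterable[tuple[AnnotatedVariant, Optional[Judgment]]],
    path: Union[str, Path],
    fields: InfoFields,
    with_judgment: bool,
) -> None:
    # materialized so contig declarations can precede the records
    items = list(items)
    contigs: list[str] = []
    for v, _ in items:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, fields, with_judgment))
        for v, j in items:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{_info_string(v, j, fields)}\n"
            )


def write_vcf(
    variants: Iterable[AnnotatedVariant],
    path: Union[str, Path],
    fields: InfoFields = InfoFields(),
) -> None:
    """Write variants as a plain-text annotated VCF (one alt per line)."""
    _write(((v, None) for v in variants), path, fields, with_judgment=False)


def write_classified_vcf(
    pairs: Iterable[tuple[AnnotatedVariant, Judgment]],
    path: Union[str, Path],
    fields: InfoFields = InfoFields(),
) -> None:
    """Write variants plus their judgments (verdict|rule|reason INFO key)."""
    _write(pairs, path, fields, with_judgment=True)


# --- calibration table -------------------------------------------------

_TABLE_COLUMNS = [
    "Gene",
    "Category",
    "PathoMafThreshold",
    "MeanPathogenicCadd",
    "MeanPopulationCadd",
    "Sens95CaddThreshold",
    "Spec95CaddThreshold",
    "PathogenicImpactDistribution",
    "BenignImpactDistribution",
    "NPathogenic",
    "NBenign",
    "MwuPValue",
]


def _dist_to_str(d: ImpactDistribution) -> str:
    if not d.defined:
        return ""
    return ",".join(repr(x) for x in d.as_tuple())


def _dist_from_str(s: Optional[str]) -> ImpactDistribution:
    if s is None or s == "" or (isinstance(s, float) and math.isnan(s)):
        return ImpactDistribution.absent()
    h, m, lo, mo = (float(x) for x in str(s).split(","))
    return ImpactDistribution(high=h, moderate=m, low=lo, modifier=mo)


def _opt_float(x) -> Optional[float]:
    if x is None or x == "" or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def write_calibration_table(
    calibrations: Mapping[str, GeneCalibration], path: Union[str, Path]
) -> None:
    """Write the gene calibration table as TSV (one row per gene)."""
    rows = []
    for gene in sorted(calibrations):
        c = calibrations[gene]
        rows.append(
            {
                "Gene": c.gene,
                "Category": c.category.value,
                "PathoMafThreshold": "" if c.patho_maf_threshold is None else repr(c.patho_maf_threshold),
                "MeanPathogenicCadd": "" if c.mean_patho_cadd is None else repr(c.mean_patho_cadd),
                "MeanPopulationCadd": "" if c.mean_benign_cadd is None else repr(c.mean_benign_cadd),
                "Sens95CaddThreshold": "" if c.sens95_cadd is None else repr(c.sens95_cadd),
                "Spec95CaddThreshold": "" if c.spec95_cadd is None else repr(c.spec95_cadd),
                "PathogenicImpactDistribution": _dist_to_str(c.patho_impact_dist),
                "BenignImpactDistribution": _dist_to_str(c.benign_impact_dist),
                "NPathogenic": c.n_patho,
                "NBenign": c.n_benign,
                "MwuPValue": "" if c.mwu_p is None else repr(c.mwu_p),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calibration_table(path: Union[str, Path]) -> dict[str, GeneCalibration]:
    """Read a gene calibration table TSV into a gene→calibration map.

    Raises on duplicate gene symbols, unknown category tokens, or missing
    required columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns and c != "BenignImpactDistribution"]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    out: dict[str, GeneCalibration] = {}
    for _, row in df.iterrows():
        gene = row["Gene"]
        if gene in out:
            raise ValueError(f"duplicate gene symbol in calibration table: {gene}")
        try:
            category = CalibrationCategory(row["Category"])
        except ValueError:
            raise ValueError(
                f"unknown calibration category {row['Category']!r} for gene {gene}"
            ) from None
        out[gene] = GeneCalibration(
            gene=gene,
            category=category,
            patho_maf_threshold=_opt_float(row["PathoMafThreshold"]),
            mean_patho_cadd=_opt_float(row["MeanPathogenicCadd"]),
            mean_benign_cadd=_opt_float(row["MeanPopulationCadd"]),
            sens95_cadd=_opt_float(row["Sens95CaddThreshold"]),
            spec95_cadd=_opt_float(row["Spec95CaddThreshold"]),
            patho_impact_dist=_dist_from_str(row["PathogenicImpactDistribution"]),
            benign_impact_dist=_dist_from_str(row.get("BenignImpactDistribution", "")),
            mwu_p=_opt_float(row["MwuPValue"]),
            n_patho=int(row["NPathogenic"]),
            n_benign=int(row["NBenign"]),
        )
    return out


# --- CGD map ------------------------------------------------------------

def read_cgd(
    path: Union[str, Path],
    gene_col: str = "GENE",
    category_col: str = "MANIFESTATION CATEGORIES",
    delimiter: str = ";",
) -> dict[str, set[str]]:
    """Read a CGD-style TSV into a gene → manifestation-category-set map.

    A leading ``#`` on the header row is tolerated (the distributed file
    has one).  Genes listed on several rows get the union of categories;
    category names are whitespace-trimmed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in (gene_col, category_col):
        if col not in df.columns:
            raise ValueError(f"CGD table missing required column {col!r}")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        gene = row[gene_col].strip()
        if not gene:
            continue
        cats = {c.strip() for c in row[category_col].split(delimiter) if c.strip()}
        out.setdefault(gene, set()).update(cats)
    return out


# --- truth sidecar ------------------------------------------------------

def write_truth_table(
    variants: Iterable[AnnotatedVariant], path: Union[str, Path]
) -> None:
    """Write a sidecar TSV of truth labels (site-keyed).

    One row per distinct site; when the same site appears repeatedly
    (e.g. a known pathogenic variant also observed in the population
    pool) the first label wins.
    """
    seen: set[tuple] = set()
    rows = []
    for v in variants:
        if v.site in seen:
            continue
        seen.add(v.site)
        rows.append(
            {
                "CHROM": v.chrom,
                "POS": v.pos,
                "REF": v.ref,
                "ALT": v.alt,
                "GENE": v.gene or "",
                "LABEL": v.label.value if v.label is not None else "",
            }
        )
    pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "GENE", "LABEL"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_table(path: Union[str, Path]) -> dict[tuple, Label]:
    """Read a truth sidecar TSV into a (chrom,pos,ref,alt) → Label map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[tuple, Label] = {}
    for _, row in df.iterrows():
        if row["LABEL"]:
            out[(row["CHROM"], int(row["POS"]), row["REF"], row["ALT"])] = Label(
                row["LABEL"]
            )
    return out
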