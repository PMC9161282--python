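"""Readers and writers for every external table the pipeline touches.

All flat files are UTF-8 tab-delimited with a header line.  CNV calls and
gene models are 0-based half-open (BED convention); VCF positions stay
1-based on the variant records.  Readers validate eagerly and raise
:class:`~xenoprio.types.ValidationError` / :class:`~xenoprio.types.FormatError`
rather than silently dropping rows, so record counts always reconcile with
input row counts.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import (
    AnnotatedVariant,
    ChemicalEntry,
    CnvCall,
    CnvClass,
    CohortFrequency,
    FormatError,
    GeneModel,
    GenePanelEntry,
    Impact,
    InteractionRecord,
    PanelCategory,
    PolyphenLabel,
    SiftLabel,
    TrioRecord,
    ValidationError,
)

_PRED_RE = re.compile(r"^\s*([A-Za-z_]+)\s*(?:\(\s*([0-9.eE+-]+)\s*\))?\s*$")


def parse_prediction(text: str, enum_cls):
    """Parse a VEP-style prediction string like ``deleterious(0.01)``.

    Returns ``(label, score)``; both ``None`` for empty/missing input.
    """
    if text is None or text == "" or text == ".":
        return None, None
    m = _PRED_RE.match(text)
    if not m:
        raise FormatError(f"unparseable prediction string: {text!r}")
    label = m.group(1)
    score = float(m.group(2)) if m.group(2) is not None else None
    try:
        return enum_cls(label), score
    except ValueError:
        raise FormatError(
            f"unknown {enum_cls.__name__} label {label!r}"
        ) from None


# ---------------------------------------------------------------------------
# gene panel


def read_panel(path) -> list[GenePanelEntry]:
    """Read a gene panel TSV with columns symbol, category, subcategory
    (optional aliases, comma-separated).  Duplicate symbols are rejected."""
    rows = _read_tsv_dicts(path, required=("symbol", "category", "subcategory"))
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):  # line numbers incl. header
        sym = row["symbol"].strip()
        if sym in seen:
            raise ValidationError(f"{path}: duplicated gene symbol {sym!r}")
        seen.add(sym)
        try:
            cat = PanelCategory(row["category"].strip())
        except ValueError:
            raise ValidationError(
                f"{path} line {i}: unknown category {row['category']!r} "
                f"for gene {sym}"
            ) from None
        aliases = tuple(
            a.strip() for a in row.get("aliases", "").split(",") if a.strip()
        )
        entries.append(
            GenePanelEntry(symbol=sym, category=cat,
                           subcategory=row["subcategory"].strip(), aliases=aliases)
        )
    return entries


def write_panel(entries: Iterable[GenePanelEntry], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["symbol", "category", "subcategory", "aliases"])
        for e in entries:
            w.writerow([e.symbol, e.category.value, e.subcategory,
                        ",".join(e.aliases)])


def read_gene_models(path) -> list[GeneModel]:
    rows = _read_tsv_dicts(path, required=("symbol", "chrom", "start", "end"))
    models = []
    seen: set[str] = set()
    for row in rows:
        if row["symbol"] in seen:
            raise ValidationError(f"{path}: duplicated gene model {row['symbol']!r}")
        seen.add(row["symbol"])
        models.append(
            GeneModel(symbol=row["symbol"], chrom=row["chrom"],
                      start=int(row["start"]), end=int(row["end"]),
                      strand=row.get("strand", "+") or "+")
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["symbol", "chrom", "start", "end", "strand"])
        for g in models:
            w.writerow([g.symbol, g.chrom, g.start, g.end, g.strand])


# ---------------------------------------------------------------------------
# variants

#: required columns of the flat variant dialect; cohort counts are carried in
#: ``ac_<label>`` / ``an_<label>`` column pairs.
FLAT_VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "gene",
                        "consequence", "impact", "sift", "polyphen")


def read_variant_table(path, dialect: str = "flat_tsv") -> list[AnnotatedVariant]:
    """Read annotated variants.

    dialect ``flat_tsv``: one row per alt allele, consequence terms
    ``&``-separated, SIFT/PolyPhen as bare labels or ``label(score)``.

    dialect ``vcf_csq``: VCF 4.x with a VEP-style pipe-delimited INFO/CSQ
    field whose subfield order is declared in the header (must include
    Allele, Consequence, IMPACT, SYMBOL, SIFT, PolyPhen).  Per-cohort counts
    come from INFO keys ``AC_<label>`` (per-alt) and ``AN_<label>``.
    Multi-allelic sites are decomposed into one record per alt allele.
    """
    if dialect == "flat_tsv":
        return _read_variants_flat(path)
    if dialect == "vcf_csq":
        return _read_variants_vcf(path)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _read_variants_flat(path) -> list[AnnotatedVariant]:
    rows = _read_tsv_dicts(path, required=FLAT_VARIANT_COLUMNS)
    if rows:
        labels = sorted(
            c[3:] for c in rows[0] if c.startswith("ac_") and f"an_{c[3:]}" in rows[0]
        )
    else:
        labels = []
    out = []
    for row in rows:
        sift, sift_score = parse_prediction(row["sift"], SiftLabel)
        poly, poly_score = parse_prediction(row["polyphen"], PolyphenLabel)
        counts = {}
        for lab in labels:
            ac_s, an_s = row.get(f"ac_{lab}", ""), row.get(f"an_{lab}", "")
            if ac_s == "" or an_s == "":
                continue
            counts[lab] = CohortFrequency(lab, int(ac_s), int(an_s))
        out.append(
            AnnotatedVariant(
                chrom=row["chrom"], pos=int(row["pos"]),
                ref=row["ref"], alt=row["alt"], gene_symbol=row["gene"],
                consequence_terms=tuple(
                    t for t in row["consequence"].split("&") if t
                ),
                impact=Impact(row["impact"]),
                sift=sift, polyphen=poly,
                sift_score=sift_score, polyphen_score=poly_score,
                cohort_counts=counts,
            )
        )
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path) -> None:
    """Write the flat_tsv dialect (round-trips through read_variant_table)."""
    labels = sorted({lab for v in variants for lab in v.cohort_counts})
    cols = list(FLAT_VARIANT_COLUMNS)
    for lab in labels:
        cols += [f"ac_{lab}", f"an_{lab}"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for v in variants:
            def fmt(label, score):
                if label is None:
                    return ""
                return label.value if score is None else f"{label.value}({score:g})"
            row = [v.chrom, v.pos, v.ref, v.alt, v.gene_symbol,
                   "&".join(v.consequence_terms), v.impact.value,
                   fmt(v.sift, v.sift_score), fmt(v.polyphen, v.polyphen_score)]
            for lab in labels:
                cf = v.cohort_counts.get(lab)
                row += ["", ""] if cf is None else [cf.ac, cf.an]
            w.writerow(row)


_CSQ_REQUIRED = ("Allele", "Consequence", "IMPACT", "SYMBOL", "SIFT", "PolyPhen")


def _read_variants_vcf(path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        desc = vcf.get_header_type("CSQ")["Description"]
    except KeyError:
        raise FormatError(f"{path}: no INFO/CSQ declaration in header") from None
    m = re.search(r"Format:\s*([\w|]+)", desc)
    if not m:
        raise FormatError(f"{path}: CSQ description lacks a Format: subfield list")
    fields = m.group(1).split("|")
    missing = [f for f in _CSQ_REQUIRED if f not in fields]
    if missing:
        raise FormatError(f"{path}: CSQ layout missing subfields {missing}")
    idx = {f: i for i, f in enumerate(fields)}

    labels = sorted(
        h["ID"][3:]
        for h in vcf.header_iter()
        if h.type == "INFO" and h["ID"].startswith("AC_")
    )

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        csq_raw = rec.INFO.get("CSQ")
        if csq_raw is None:
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks CSQ")
        blocks = [b.split("|") for b in csq_raw.split(",")]
        for ai, alt in enumerate(rec.ALT):
            match = [b for b in blocks if b[idx["Allele"]] == alt]
            if not match and len(rec.ALT) == 1 and len(blocks) == 1:
                match = blocks  # single-allele records may use trimmed alleles
            if not match:
                raise FormatError(
                    f"{path}: no CSQ block for allele {alt} at {rec.CHROM}:{rec.POS}"
                )
            b = match[0]
            sift, sift_score = parse_prediction(b[idx["SIFT"]], SiftLabel)
            poly, poly_score = parse_prediction(b[idx["PolyPhen"]], PolyphenLabel)
            counts = {}
            for lab in labels:
                ac = rec.INFO.get(f"AC_{lab}")
                an = rec.INFO.get(f"AN_{lab}")
                if ac is None or an is None:
                    continue
                if isinstance(ac, (tuple, list)):
                    ac = ac[ai]
                counts[lab] = CohortFrequency(lab, int(ac), int(an))
            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    gene_symbol=b[idx["SYMBOL"]],
                    consequence_terms=tuple(
                        t for t in b[idx["Consequence"]].split("&") if t
                    ),
                    impact=Impact(b[idx["IMPACT"]]),
                    sift=sift, polyphen=poly,
                    sift_score=sift_score, polyphen_score=poly_score,
                    cohort_counts=counts,
                )
            )
    return out


def write_variants_vcf(variants: Sequence[AnnotatedVariant], path) -> None:
    """Write variants as a minimal VCF 4.2 with a VEP-style CSQ INFO field
    and per-cohort AC_<label>/AN_<label> INFO counts (biallelic records)."""
    labels = sorted({lab for v in variants for lab in v.cohort_counts})
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)

    def fmt_pred(label, score):
        if label is None:
            return ""
        return label.value if score is None else f"{label.value}({score:g})"

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations. Format: Allele|Consequence|IMPACT|SYMBOL|SIFT|PolyPhen">\n'
        )
        for lab in labels:
            fh.write(f'##INFO=<ID=AC_{lab},Number=A,Type=Integer,'
                     f'Description="Alt allele count, {lab}">\n')
            fh.write(f'##INFO=<ID=AN_{lab},Number=1,Type=Integer,'
                     f'Description="Called alleles, {lab}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (chroms.index(x.chrom), x.pos)):
            csq = "|".join([
                v.alt, "&".join(v.consequence_terms), v.impact.value,
                v.gene_symbol, fmt_pred(v.sift, v.sift_score),
                fmt_pred(v.polyphen, v.polyphen_score),
            ])
            info = [f"CSQ={csq}"]
            for lab in labels:
                cf = v.cohort_counts.get(lab)
                if cf is not None:
                    info.append(f"AC_{lab}={cf.ac}")
                    info.append(f"AN_{lab}={cf.an}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     + ";".join(info) + "\n")


def read_genotypes(path) -> dict[str, list]:
    """Read per-variant genotype calls (variant_key, sample_id, alt_count,
    dp, gq); alt_count '.' or empty means a missing genotype."""
    from .snv import GenotypeCall

    rows = _read_tsv_dicts(
        path, required=("variant_key", "sample_id", "alt_count", "dp", "gq"))
    out: dict[str, list] = {}
    for row in rows:
        ac = row["alt_count"]
        out.setdefault(row["variant_key"], []).append(
            GenotypeCall(
                sample_id=row["sample_id"],
                alt_count=None if ac in ("", ".") else int(ac),
                dp=int(row["dp"]), gq=int(row["gq"]),
            )
        )
    return out


def write_genotypes(genotypes: dict[str, Sequence], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_key", "sample_id", "alt_count", "dp", "gq"])
        for key in sorted(genotypes):
            for c in genotypes[key]:
                w.writerow([key, c.sample_id,
                            "." if c.alt_count is None else c.alt_count,
                            c.dp, c.gq])


# ---------------------------------------------------------------------------
# CNVs

CNV_COLUMNS = ("chrom", "start", "end", "sample_id", "cnv_class",
               "cohort", "dataset_frequency")


def read_cnv_table(path, cohort: str = "") -> list[CnvCall]:
    """Read a BED-like CNV table.

    Accepts a headered TSV (columns of :data:`CNV_COLUMNS`, the last two
    optional) or a headerless BED-like file with positional columns
    chrom, start, end, sample_id, cnv_class[, cohort[, dataset_frequency]].
    ``cohort`` supplies a default cohort label for rows that carry none.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    first = re.split(r"\s+", lines[0].strip())
    has_header = first[0].lstrip("#").lower() == "chrom"
    out = []
    for ln in lines[1:] if has_header else lines:
        parts = re.split(r"\s+", ln.strip())
        if len(parts) < 5:
            raise FormatError(f"{path}: CNV row with < 5 columns: {ln!r}")
        freq = None
        if len(parts) >= 7 and parts[6] not in ("", "."):
            freq = float(parts[6])
        try:
            klass = CnvClass(parts[4])
        except ValueError:
            raise ValidationError(
                f"{path}: unknown CNV class {parts[4]!r} in row {ln!r}"
            ) from None
        out.append(
            CnvCall(
                sample_id=parts[3],
                cohort=parts[5] if len(parts) >= 6 and parts[5] else cohort,
                chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                cnv_class=klass, dataset_frequency=freq,
            )
        )
    return out


def write_cnv_table(cnvs: Iterable[CnvCall], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CNV_COLUMNS)
        for c in cnvs:
            w.writerow([c.chrom, c.start, c.end, c.sample_id, c.cnv_class.value,
                        c.cohort,
                        "" if c.dataset_frequency is None else repr(c.dataset_frequency)])


# ---------------------------------------------------------------------------
# pedigrees and carriage


def read_ped(path) -> list[TrioRecord]:
    """Read a 6-column PED file; parent code "0" becomes an absent parent.

    One TrioRecord is emitted per affected individual (phenotype 2), or —
    when no phenotype column distinguishes anyone — per individual with at
    least one listed parent.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = re.split(r"\s+", ln.strip())
            if len(parts) < 6:
                raise FormatError(f"{path}: PED row with < 6 columns: {ln!r}")
            rows.append(parts)
    any_affected = any(r[5] == "2" for r in rows)
    trios = []
    for fam, iid, father, mother, _sex, pheno in (r[:6] for r in rows):
        is_proband = pheno == "2" if any_affected else (father != "0" or mother != "0")
        if not is_proband:
            continue
        trios.append(
            TrioRecord(
                proband_id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                family_id=fam,
            )
        )
    return trios


def write_ped(trios: Iterable[TrioRecord], path, all_members: bool = True) -> None:
    """Write trios as PED; parents get their own unaffected rows."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for t in trios:
            fam = t.family_id or t.proband_id
            if all_members:
                if t.father_id:
                    fh.write(f"{fam}\t{t.father_id}\t0\t0\t1\t1\n")
                if t.mother_id:
                    fh.write(f"{fam}\t{t.mother_id}\t0\t0\t2\t1\n")
            fh.write(
                f"{fam}\t{t.proband_id}\t{t.father_id or 0}\t{t.mother_id or 0}\t0\t2\n"
            )


def read_carriage(path) -> dict[str, frozenset[str]]:
    """Read a person -> carried-key table (columns person_id, carried_key).

    A person may appear with an empty key to declare "genotyped, carries
    nothing" — needed to distinguish absent data from absent carriage.
    """
    rows = _read_tsv_dicts(path, required=("person_id", "carried_key"))
    acc: dict[str, set[str]] = {}
    for row in rows:
        acc.setdefault(row["person_id"], set())
        if row["carried_key"]:
            acc[row["person_id"]].add(row["carried_key"])
    return {p: frozenset(s) for p, s in acc.items()}


def write_carriage(carriage: dict[str, frozenset[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["person_id", "carried_key"])
        for person in sorted(carriage):
            keys = sorted(carriage[person])
            if not keys:
                w.writerow([person, ""])
            for k in keys:
                w.writerow([person, k])


def attach_carriage(trios: Sequence[TrioRecord],
                    carriage: dict[str, frozenset[str]]) -> list[TrioRecord]:
    """Attach per-person carried-key sets to trio records (new records)."""
    out = []
    for t in trios:
        members = [t.proband_id, t.mother_id, t.father_id]
        carried = {m: carriage[m] for m in members if m is not None and m in carriage}
        out.append(
            TrioRecord(proband_id=t.proband_id, mother_id=t.mother_id,
                       father_id=t.father_id, family_id=t.family_id,
                       carried=carried)
        )
    return out


# ---------------------------------------------------------------------------
# interactions and chemicals

CTD_COLUMNS = ("ChemicalName", "ChemicalID", "GeneSymbol", "Organism", "PubMedIDs")


def read_ctd_tsv(path) -> list[InteractionRecord]:
    """Read a CTD-export-shaped interaction TSV.

    Organism strings are kept verbatim (the species filter is downstream);
    a ``MESH:`` prefix on ChemicalID is stripped; PubMedIDs are
    ``|``-separated.
    """
    rows = _read_tsv_dicts(path, required=CTD_COLUMNS)
    out = []
    for row in rows:
        mesh = row["ChemicalID"].strip()
        if mesh.upper().startswith("MESH:"):
            mesh = mesh[5:]
        pmids = frozenset(p for p in row["PubMedIDs"].split("|") if p.strip())
        out.append(
            InteractionRecord(
                gene_symbol=row["GeneSymbol"].strip(),
                chemical_name=row["ChemicalName"].strip(),
                chemical_mesh_id=mesh,
                organism=row["Organism"].strip(),
                pmids=pmids,
                action=row.get("InteractionActions", "").strip(),
            )
        )
    return out


def write_ctd_tsv(records: Iterable[InteractionRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(CTD_COLUMNS) + ["InteractionActions"])
        for r in records:
            w.writerow([r.chemical_name, f"MESH:{r.chemical_mesh_id}",
                        r.gene_symbol, r.organism, "|".join(sorted(r.pmids)),
                        r.action])


def read_chemicals(path) -> list[ChemicalEntry]:
    rows = _read_tsv_dicts(path, required=("name", "mesh_id", "group"))
    seen: set[str] = set()
    out = []
    for row in rows:
        if row["mesh_id"] in seen:
            raise ValidationError(f"{path}: duplicated MeSH id {row['mesh_id']!r}")
        seen.add(row["mesh_id"])
        out.append(ChemicalEntry(name=row["name"].strip(),
                                 mesh_id=row["mesh_id"].strip(),
                                 group=row["group"].strip()))
    return out


def write_chemicals(chemicals: Iterable[ChemicalEntry], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "mesh_id", "group"])
        for c in chemicals:
            w.writerow([c.name, c.mesh_id, c.group])


# ---------------------------------------------------------------------------


def _read_tsv_dicts(path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        return [
            {k: (v if v is not None else "") for k, v in row.items() if k is not None}
            for row in reader
        ]
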