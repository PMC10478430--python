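"""File readers/writers and the packaged in-text fixtures.

Tabular dialect: UTF-8; tab-separated for mutation tables, comma-separated
for Ct and RPPA tables; '.' decimal separator; literal header row required.

Three fixtures transcribe the published tables:

* ``table1`` - the somatic mutation profile of 22 primary/metastasis
  pairs (60 loci; presence/absence only, no allele frequencies);
* ``table2`` - high/normal/low miRNA expression category pairs for
  21 cases x 6 miRNAs;
* ``table3`` - primary-to-metastasis relative-expression (PM-RE) ratios
  for the same 21 cases x 6 miRNAs, exactly as printed.
"""

from __future__ import annotations

import json
import os
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import CtRecord, MutationCall, RppaMeasurement, TumourPairRecord
from .errors import FixtureLookupError, SchemaError, ValidationError

FIXTURE_FILES = {
    "table1": "table1_mutations.tsv",
    "table2": "table2_mirna_categories.csv",
    "table3": "table3_pm_re.csv",
}

MUTATION_COLUMNS = ("case_id", "role", "gene", "hgvs_c", "maf", "tc")
CT_COLUMNS = ("sample_id", "role", "mirna_id", "ct_reference")
RPPA_COLUMNS = ("sample_id", "role", "marker", "raw_signal", "total_protein_signal")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# cohort tables (synthetic or user-supplied, MAF-bearing)

def read_mutation_table(path) -> tuple[list[MutationCall], list[TumourPairRecord]]:
    """Read a long-format mutation TSV into calls plus pair records.

    Required columns: case_id, role, gene, hgvs_c, maf, tc.  ``maf`` empty
    or 0 encodes an explicit wild-type observation.  Optional codon/exon
    columns are kept; any further columns become annotations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MUTATION_COLUMNS, path)
    extra = [c for c in df.columns if c not in MUTATION_COLUMNS + ("codon", "exon")]
    calls: list[MutationCall] = []
    tc_by_case: dict[str, dict[str, float]] = {}
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        maf_raw = rec["maf"].strip()
        maf = float(maf_raw) if maf_raw else 0.0
        if not (0.0 <= maf <= 1.0):
            raise ValidationError(f"{path}:{i}: maf {maf} outside [0, 1]")
        key = (rec["case_id"], rec["role"], rec["gene"], rec["hgvs_c"])
        if key in seen:
            raise ValidationError(f"{path}:{i}: duplicate call {key}")
        seen.add(key)
        calls.append(MutationCall(
            case_id=rec["case_id"], role=rec["role"], gene=rec["gene"],
            hgvs_c=rec["hgvs_c"], present=maf > 0, maf=maf,
            codon=rec.get("codon") or None, exon=rec.get("exon") or None,
            annotations={c: rec[c] for c in extra},
        ))
        tc_by_case.setdefault(rec["case_id"], {})[rec["role"]] = float(rec["tc"])
    pairs = []
    for case_id, tcs in tc_by_case.items():
        if set(tcs) == {"primary", "metastasis"}:
            pairs.append(TumourPairRecord(case_id, tcs["primary"], tcs["metastasis"]))
    return calls, pairs


def write_mutation_table(calls: Sequence[MutationCall],
                         pairs: Sequence[TumourPairRecord], path) -> None:
    """Inverse of :func:`read_mutation_table` (field-by-field round-trip)."""
    tc = {p.case_id: p for p in pairs}
    extra = sorted({k for c in calls for k in c.annotations})
    rows = []
    for c in calls:
        row = {
            "case_id": c.case_id, "role": c.role, "gene": c.gene,
            "hgvs_c": c.hgvs_c, "maf": repr(float(c.maf or 0.0)),
            "tc": repr(float(tc[c.case_id].tc(c.role))),
            "codon": c.codon or "", "exon": c.exon or "",
        }
        row.update({k: c.annotations.get(k, "") for k in extra})
        rows.append(row)
    cols = list(MUTATION_COLUMNS) + ["codon", "exon"] + extra
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> list[TumourPairRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("case_id", "tc_primary", "tc_metastasis"), path)
    return [TumourPairRecord(r.case_id, float(r.tc_primary), float(r.tc_metastasis))
            for r in df.itertuples(index=False)]


def write_pair_table(pairs: Sequence[TumourPairRecord], path) -> None:
    pd.DataFrame(
        [{"case_id": p.case_id, "tc_primary": repr(p.tc_primary),
          "tc_metastasis": repr(p.tc_metastasis)} for p in pairs]
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> list[CtRecord]:
    """Read a Ct CSV: sample_id, role, mirna_id, ct_rep1..ct_repK, ct_reference."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CT_COLUMNS, path)
    rep_cols = sorted(c for c in df.columns if c.startswith("ct_rep"))
    if not rep_cols:
        raise SchemaError(f"{path}: need at least one ct_rep<k> column")
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        reps = tuple(float(rec[c]) for c in rep_cols if rec[c].strip())
        records.append(CtRecord(
            sample_id=rec["sample_id"], role=rec["role"], mirna_id=rec["mirna_id"],
            ct_replicates=reps, ct_reference=float(rec["ct_reference"]),
        ))
    return records


def write_ct_table(records: Sequence[CtRecord], path) -> None:
    k = max(len(r.ct_replicates) for r in records)
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "role": r.role, "mirna_id": r.mirna_id}
        for i in range(k):
            row[f"ct_rep{i + 1}"] = (repr(r.ct_replicates[i])
                                     if i < len(r.ct_replicates) else "")
        row["ct_reference"] = repr(r.ct_reference)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rppa_table(path) -> list[RppaMeasurement]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, RPPA_COLUMNS, path)
    return [RppaMeasurement(r.sample_id, r.role, r.marker,
                            float(r.raw_signal), float(r.total_protein_signal))
            for r in df.itertuples(index=False)]


def write_rppa_table(measurements: Sequence[RppaMeasurement], path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "role": m.role, "marker": m.marker,
          "raw_signal": repr(m.raw_signal),
          "total_protein_signal": repr(m.total_protein_signal)}
         for m in measurements]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF ingestion

def read_vcf_pair(vcf_primary, vcf_metastasis,
                  purity: TumourPairRecord) -> list[MutationCall]:
    """Read one VCF per tumour role into mutation calls.

    The mutant allele fraction is taken from INFO/AF, then FORMAT/AF, then
    computed as alt/(ref+alt) from FORMAT/AD.  Records providing none of
    these are an error.  Multi-allelic records are split per ALT.  Loci are
    keyed by the INFO/GENE annotation when present, else CHROM:POS:REF:ALT.
    """
    from cyvcf2 import VCF

    calls: list[MutationCall] = []
    for role, path in (("primary", vcf_primary), ("metastasis", vcf_metastasis)):
        for variant in VCF(str(path)):
            alts = variant.ALT or []
            for ai, alt in enumerate(alts):
                af = _variant_af(variant, ai, path)
                gene = variant.INFO.get("GENE")
                key = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
                calls.append(MutationCall(
                    case_id=purity.case_id, role=role,
                    gene=gene if gene else key, hgvs_c=key,
                    present=af > 0, maf=af,
                ))
    return calls


def _variant_af(variant, alt_index: int, path) -> float:
    af = variant.INFO.get("AF")
    if af is not None:
        if isinstance(af, tuple):
            af = af[alt_index]
        return float(af)
    try:
        fmt_af = variant.format("AF")
    except KeyError:
        fmt_af = None
    if fmt_af is not None:
        return float(fmt_af[0][alt_index])
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        depths = ad[0]
        total = float(depths.sum())
        if total > 0:
            return float(depths[alt_index + 1]) / total
    raise ValidationError(
        f"{path}: record {variant.CHROM}:{variant.POS} has neither AF nor AD"
    )


# ---------------------------------------------------------------------------
# packaged fixtures

def _fixture_path(name: str):
    if name not in FIXTURE_FILES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {sorted(FIXTURE_FILES)}"
        )
    return resources.files("metconcord") / "_fixtures" / FIXTURE_FILES[name]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture.

    ``table1`` -> one row per mutation locus (60 rows) with '+'/'Wild'
    presence columns; the full 22-case universe (including the two
    mutation-free cases) is in ``df.attrs["case_ids"]``.
    ``table2`` -> 21 pairs x MultiIndex (miRNA, role) category frame.
    ``table3`` -> 21 pairs x 6 miRNAs numeric PM-RE matrix, as printed.
    """
    with resources.as_file(_fixture_path(name)) as path:
        if name == "table1":
            df = pd.read_csv(path, sep="\t", dtype=str)
            case_ids = list(dict.fromkeys(df["case_id"]))
            loci = df[df["gene"] != "."].reset_index(drop=True)
            loci.attrs["case_ids"] = case_ids
            return loci
        if name == "table2":
            long = pd.read_csv(path, dtype=str)
            wide = long.pivot(index="pair_id", columns="mirna_id",
                              values=["primary", "metastasis"])
            wide = wide.reorder_levels([1, 0], axis=1).sort_index(axis=1)
            order = list(dict.fromkeys(long["pair_id"]))
            return wide.loc[order].map(str.lower)
        df = pd.read_csv(path, index_col="pair_id")
        return df


def table1_mutation_calls() -> tuple[list[MutationCall], list[str]]:
    """Expand the table1 fixture into per-role presence calls.

    Returns the 120 calls (60 loci x 2 roles) and the 22-case universe.
    """
    df = load_fixture("table1")
    calls = []
    for row in df.itertuples(index=False):
        ann = {"state": row.state, "sift": row.sift,
               "polyphen": row.polyphen, "fathmm": row.fathmm}
        for role, flag in (("primary", row.primary), ("metastasis", row.metastasis)):
            calls.append(MutationCall(
                case_id=row.case_id, role=role, gene=row.gene, hgvs_c=row.hgvs_c,
                present=flag.strip() == "+", maf=None,
                codon=row.codon, exon=row.exon, annotations=ann,
            ))
    return calls, df.attrs["case_ids"]


# ---------------------------------------------------------------------------
# report writing

def write_reports(results: Mapping, outdir) -> list[Path]:
    """Write per-entity tables plus a machine-readable summary.

    ``results`` maps names to DataFrames (written as ``<name>.tsv``) or to
    JSON-serialisable scalars/dicts (collected into ``summary.json``).
    Writes are atomic (tmp file + rename); re-running overwrites.
    """
    outdir = Path(outdir)
    if outdir.exists() and not outdir.is_dir():
        raise OSError(f"{outdir} exists and is not a directory")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summary: dict = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            target = outdir / f"{name}.tsv"
            tmp = target.with_suffix(".tsv.tmp")
            obj.to_csv(tmp, sep="\t", index=False)
            os.replace(tmp, target)
            written.append(target)
        else:
            summary[name] = obj
    target = outdir / "summary.json"
    tmp = target.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    os.replace(tmp, target)
    written.append(target)
    return written
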