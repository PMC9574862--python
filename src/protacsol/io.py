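"""Readers, writers and dataset validation.

Tables are comma-separated UTF-8 with a mandatory header row and decimal
points. Instrument exports using decimal commas must be normalised first
(``read_compounds(..., decimal_comma=True)``). Structures come from SMILES
columns or SDF files (V2000/V3000) parsed with RDKit. Censored solubility
values are written with the literal sentinel ``ND`` (not detectable).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem.Descriptors import MolWt

from .datatypes import (
    ColumnSystem,
    CompoundRecord,
    Dataset,
    DescriptorProfile,
    GskClass,
    RetentionPoint,
    RetentionSeries,
    Role,
    SolubilityMeasurement,
)
from .errors import SchemaError, StructureError

ND_SENTINEL = "ND"

#: descriptor columns emitted by write_profiles, in order
PROFILE_COLUMNS = [
    "compound_id",
    "nc",
    "tpsa",
    "phi",
    "brlogd",
    "log_kw_iam",
    "clog_kw_iam",
    "delta_log_kw_iam",
    "epsa",
    "extrapolation_r2",
    "conc_mg_ml",
    "log_s",
    "s_micromolar",
    "sd",
    "rsd",
    "gsk_class",
]

# mw within this margin of the structure-derived value passes validation;
# larger gaps (salts, solvates) raise a finding but are never auto-resolved
MW_TOLERANCE_G_MOL = 0.5


def parse_smiles(smiles: str, compound_id: str = "?") -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"compound {compound_id!r}: SMILES {smiles!r} does not parse")
    return mol


def read_compounds(
    path: Union[str, Path],
    *,
    decimal_comma: bool = False,
) -> list[CompoundRecord]:
    """Read compound records from a CSV (columns ``id``, ``smiles``,
    optional ``name``, ``mw``, ``role``, ``charge_note``) or an SDF file.

    Missing molecular weights are computed from the structure (average
    atomic masses). Order is preserved.
    """
    path = Path(path)
    if path.suffix.lower() in {".sdf", ".sd", ".mol"}:
        return _read_compounds_sdf(path)
    return _read_compounds_csv(path, decimal_comma=decimal_comma)


def _read_compounds_csv(path: Path, *, decimal_comma: bool) -> list[CompoundRecord]:
    df = pd.read_csv(path, dtype=str, decimal="," if decimal_comma else ".")
    for required in ("id", "smiles"):
        if required not in df.columns:
            raise SchemaError(f"{path}: missing required column {required!r}")
    records = []
    for _, row in df.iterrows():
        cid = str(row["id"]).strip()
        smiles = str(row["smiles"]).strip()
        mol = parse_smiles(smiles, cid)
        mw = None
        if "mw" in df.columns and not _blank(row.get("mw")):
            mw = float(str(row["mw"]).replace(",", "."))
        if mw is None:
            mw = MolWt(mol)
        role = Role(str(row["role"]).strip()) if "role" in df.columns and not _blank(row.get("role")) else Role.PROTAC
        records.append(
            CompoundRecord(
                id=cid,
                smiles=smiles,
                name=str(row["name"]).strip() if "name" in df.columns and not _blank(row.get("name")) else "",
                mw=mw,
                role=role,
                charge_note=str(row["charge_note"]).strip()
                if "charge_note" in df.columns and not _blank(row.get("charge_note"))
                else "",
            )
        )
    _check_unique_ids(records)
    return records


def _read_compounds_sdf(path: Path) -> list[CompoundRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: record {i} does not parse")
        props = mol.GetPropsAsDict()
        cid = str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"))
        records.append(
            CompoundRecord(
                id=cid,
                smiles=Chem.MolToSmiles(mol),
                name=str(props.get("name", "")),
                mw=float(props["mw"]) if "mw" in props else MolWt(mol),
                role=Role(str(props["role"])) if "role" in props else Role.PROTAC,
            )
        )
    _check_unique_ids(records)
    return records


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() in {"", "nan"}


def _check_unique_ids(records: Iterable[CompoundRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SchemaError(f"duplicate compound id {r.id!r}")
        seen.add(r.id)


def read_retention(path: Union[str, Path]) -> list[RetentionSeries]:
    """Read a retention-time table (columns ``compound_id``, ``system``,
    ``percent_organic``, ``t_R_min``, ``t0_min``, ``replicate``) and group
    rows into one series per (compound, system)."""
    df = pd.read_csv(path)
    required = {"compound_id", "system", "percent_organic", "t_R_min", "t0_min"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    series: dict[tuple[str, str], RetentionSeries] = {}
    for _, row in df.iterrows():
        key = (str(row["compound_id"]), str(row["system"]))
        if key not in series:
            series[key] = RetentionSeries(compound_id=key[0], system=ColumnSystem(key[1]))
        series[key].points.append(
            RetentionPoint(
                percent_organic=float(row["percent_organic"]),
                t_r=float(row["t_R_min"]),
                t0=float(row["t0_min"]),
                replicate=int(row["replicate"]),
            )
        )
    return list(series.values())


def write_profiles(dataset: Dataset, path: Union[str, Path, _io.TextIOBase]) -> pd.DataFrame:
    """Write one row per compound with all descriptor and solubility fields.

    Missing values are empty cells; a censored solubility is rendered as the
    ``ND`` sentinel in the numeric solubility columns. Returns the frame
    written. Re-reading with :func:`read_profiles` reproduces exact fields.
    """
    rows = []
    for comp in dataset.compounds:
        prof = dataset.descriptors.get(comp.id, DescriptorProfile(compound_id=comp.id))
        sol = dataset.solubility.get(comp.id)
        row: dict[str, object] = {"compound_id": comp.id}
        for col in ("nc", "tpsa", "phi", "brlogd", "log_kw_iam", "clog_kw_iam",
                    "delta_log_kw_iam", "epsa", "extrapolation_r2"):
            row[col] = getattr(prof, col)
        if sol is None:
            row.update({c: None for c in ("conc_mg_ml", "log_s", "s_micromolar", "sd", "rsd", "gsk_class")})
        elif sol.censored:
            row.update({"conc_mg_ml": ND_SENTINEL, "log_s": ND_SENTINEL,
                        "s_micromolar": ND_SENTINEL, "sd": sol.sd, "rsd": sol.rsd,
                        "gsk_class": sol.gsk_class.value if sol.gsk_class else None})
        else:
            row.update({"conc_mg_ml": sol.conc_mg_ml, "log_s": sol.log_s,
                        "s_micromolar": sol.s_micromolar, "sd": sol.sd, "rsd": sol.rsd,
                        "gsk_class": sol.gsk_class.value if sol.gsk_class else None})
        rows.append(row)
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_profiles(path: Union[str, Path]) -> pd.DataFrame:
    """Read a profile table written by :func:`write_profiles`; ``ND`` cells
    become NaN with ``censored`` True."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    sol_cols = ["conc_mg_ml", "log_s", "s_micromolar"]
    censored = pd.Series(False, index=df.index)
    for col in sol_cols:
        if df[col].dtype == object:
            censored |= df[col].astype(str).str.strip() == ND_SENTINEL
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["censored"] = censored
    return df


@dataclass
class ValidationFinding:
    kind: str        # dangling_reference | duplicate_id | unit_anomaly | structure
    compound_id: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[ValidationFinding]:
        return [f for f in self.findings if f.kind == kind]


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report duplicate ids, dangling references and unit anomalies.

    Report-only: the dataset is never modified. A stated molecular weight
    more than 0.5 g/mol from the structure-derived value is flagged as a
    unit anomaly (possible salt/solvate), not corrected.
    """
    report = ValidationReport()
    ids = [c.id for c in dataset.compounds]
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            report.findings.append(ValidationFinding("duplicate_id", cid, f"compound id {cid!r} occurs more than once"))
        seen.add(cid)
    known = set(ids)
    for series in dataset.retention:
        if series.compound_id not in known:
            report.findings.append(
                ValidationFinding("dangling_reference", series.compound_id,
                                  f"retention series references unknown id {series.compound_id!r}"))
    for cid in list(dataset.solubility) + list(dataset.descriptors):
        if cid not in known:
            report.findings.append(
                ValidationFinding("dangling_reference", cid, f"entry references unknown id {cid!r}"))
    for comp in dataset.compounds:
        if comp.mw is not None and comp.mw <= 0:
            report.findings.append(ValidationFinding("unit_anomaly", comp.id, f"non-positive mw {comp.mw}"))
        if comp.smiles:
            try:
                mol = parse_smiles(comp.smiles, comp.id)
            except StructureError as exc:
                report.findings.append(ValidationFinding("structure", comp.id, str(exc)))
                continue
            if comp.mw is not None and comp.mw > 0:
                computed = MolWt(mol)
                if abs(comp.mw - computed) > MW_TOLERANCE_G_MOL:
                    report.findings.append(
                        ValidationFinding(
                            "unit_anomaly", comp.id,
                            f"stated mw {comp.mw:.2f} differs from structure-derived "
                            f"{computed:.2f} by more than {MW_TOLERANCE_G_MOL} g/mol "
                            "(salt or solvate?)"))
    return report


def read_manifest(path: Union[str, Path]) -> Dataset:
    """Assemble a dataset from a YAML manifest naming member files.

    Recognised keys: ``compounds`` (CSV/SDF), ``retention`` (CSV),
    ``profiles`` (CSV from :func:`write_profiles`). Paths are resolved
    relative to the manifest.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh) or {}
    base = path.parent
    ds = Dataset()
    if "compounds" in manifest:
        ds.compounds = read_compounds(base / manifest["compounds"])
    if "retention" in manifest:
        ds.retention = read_retention(base / manifest["retention"])
    if "profiles" in manifest:
        df = read_profiles(base / manifest["profiles"])
        if "compounds" not in manifest:
            # structure-less datasets (e.g. synthetic panels): compound
            # records are derived from the profile table
            ds.compounds = [CompoundRecord(id=str(cid)) for cid in df["compound_id"]]
        for _, row in df.iterrows():
            cid = row["compound_id"]
            prof = DescriptorProfile(compound_id=cid)
            for col in ("tpsa", "phi", "brlogd", "log_kw_iam", "clog_kw_iam",
                        "delta_log_kw_iam", "epsa", "extrapolation_r2"):
                val = row[col]
                if pd.notna(val):
                    setattr(prof, col, float(val))
            if pd.notna(row["nc"]):
                prof.nc = int(row["nc"])
            ds.descriptors[cid] = prof
            if row["censored"] or pd.notna(row["log_s"]):
                ds.solubility[cid] = SolubilityMeasurement(
                    compound_id=cid,
                    censored=bool(row["censored"]),
                    conc_mg_ml=None if row["censored"] or pd.isna(row["conc_mg_ml"]) else float(row["conc_mg_ml"]),
                    log_s=None if row["censored"] or pd.isna(row["log_s"]) else float(row["log_s"]),
                    s_micromolar=None if row["censored"] or pd.isna(row["s_micromolar"]) else float(row["s_micromolar"]),
                    gsk_class=GskClass(row["gsk_class"]) if isinstance(row.get("gsk_class"), str) else None,
                )
    return ds
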