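"""Cohort orchestration: per-case measurements, statistics grids, reports.

Runs every measurement module per case, assembles the outcome-by-covariate
test grids (dementia status and sex via Mann-Whitney U, age / fixation time
/ postmortem interval via Spearman's rho), applies Benjamini-Hochberg FDR
separately within each analysis family (head / total / ratio for lengths,
offset-by-reference for the border), and writes deterministic TSV/JSON
reports. Tests involving sex, age, fixation time and postmortem interval
are restricted to cases without dementia; dementia-status tests use all
cases.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict

import pandas as pd

from . import border as border_mod
from . import digitations as dig_mod
from . import extent as extent_mod
from . import srlm_projection as srlm_mod
from . import subicular as sub_mod
from .core_volume import (
    CoverageMask,
    LabelVolume,
    Landmarks,
    SubfieldSchema,
    load_label_volume,
)
from .errors import HippomorphError
from .stats import StatResult, adjust_within_families, mann_whitney_u, spearman_rho

SUBFIELD_ORDER = ("SUB", "PrS", "PaS", "CA1", "CA2", "CA3", "DG", "SRLM")
TAIL_LABELS = ("SUB", "CA1", "CA2", "CA3", "DG")
APPEARANCE_LABELS = ("SUB", "CA1", "PrS", "DG", "CA3", "PaS", "CA2")

COVARIATE_TESTS = (
    ("dementia", "U", False),  # (covariate, test, restrict_to_non_dementia)
    ("sex", "U", True),
    ("age", "rho", True),
    ("fixation_days", "rho", True),
    ("pmi_hours", "rho", True),
)


def measure_case(
    case_id: str,
    volume: LabelVolume,
    landmarks: Landmarks,
    coverage: CoverageMask | None = None,
) -> dict:
    """All per-case measurements, with per-assay failures logged as QC notes."""
    out: dict = {"case_id": case_id, "qc": []}

    def guarded(name, fn):
        try:
            out[name] = fn()
        except (HippomorphError, ValueError) as exc:
            out[name] = None
            out["qc"].append(f"{name}: {exc}")

    if coverage is not None and coverage.longest_gap() >= 5:
        out["qc"].append("coverage: five or more consecutive uncovered slices")

    guarded("lengths", lambda: extent_mod.total_length_and_ratio(landmarks, volume.spacing))
    guarded(
        "appearance",
        lambda: extent_mod.appearance_order(volume, APPEARANCE_LABELS, landmarks, coverage),
    )
    guarded(
        "extents",
        lambda: [
            extent_mod.extent_record(volume, lbl, landmarks, coverage)
            for lbl in SUBFIELD_ORDER
        ],
    )
    if landmarks.posterior_tip_z is not None:
        guarded(
            "tail_presence",
            lambda: extent_mod.tail_presence(volume, TAIL_LABELS, landmarks, coverage),
        )
        guarded("subicular", lambda: sub_mod.subicular_profile(volume, landmarks))
        guarded("srlm", lambda: srlm_mod.srlm_profile(volume, landmarks))
    guarded(
        "border",
        lambda: border_mod.measure_at_offsets(volume, landmarks, coverage=coverage),
    )

    def _digitations():
        z = dig_mod.anterior_ca3_slice(volume, coverage)
        if z is None:
            return None
        profile = dig_mod.digitation_profile(dig_mod.footprint_mask(volume, z), z=z)
        strip = dig_mod.ca3_superior_strip(volume, z)
        record = dig_mod.classify_ca3(profile, strip)
        return {"z": z, "n_digitations": profile.n_digitations, "record": record}

    guarded("digitations", _digitations)
    return out


# ---------------------------------------------------------------------------
# statistics grids
# ---------------------------------------------------------------------------

def _is_dementia(v) -> bool:
    return str(v).strip().lower() in ("yes", "true", "1", "dementia")


def _run_tests(
    outcome_name: str,
    family: str,
    values: pd.Series,
    covariates: pd.DataFrame,
) -> list[StatResult]:
    """The five-covariate test row for one outcome (one analysis family)."""
    df = covariates.join(values.rename("outcome"), how="inner").dropna(subset=["outcome"])
    dementia = df["dementia"].map(_is_dementia)
    results = []
    for cov, test, restrict in COVARIATE_TESTS:
        sub = df[~dementia] if restrict else df
        sub = sub.dropna(subset=[cov] if cov != "dementia" else [])
        note = ""
        stat = p = None
        try:
            if test == "U":
                if cov == "dementia":
                    ga = sub.loc[dementia[sub.index], "outcome"].to_numpy()
                    gb = sub.loc[~dementia[sub.index], "outcome"].to_numpy()
                else:
                    key = sub[cov].astype(str).str.upper()
                    levels = sorted(key.unique())
                    if len(levels) != 2:
                        raise ValueError(f"{cov}: need exactly two groups")
                    ga = sub.loc[key == levels[0], "outcome"].to_numpy()
                    gb = sub.loc[key == levels[1], "outcome"].to_numpy()
                if min(len(ga), len(gb)) < 2:
                    raise ValueError("insufficient n")
                stat, p = mann_whitney_u(ga, gb)
                n = len(ga) + len(gb)
            else:
                x = sub[cov].astype(float).to_numpy()
                y = sub["outcome"].astype(float).to_numpy()
                stat, p = spearman_rho(x, y)
                n = len(x)
        except ValueError as exc:
            note = str(exc)
            n = len(sub)
        results.append(
            StatResult(outcome_name, cov, test, stat, p, family, None, n, note)
        )
    return results


def length_statistics(lengths: pd.DataFrame, covariates: pd.DataFrame) -> list[StatResult]:
    """Head / total / ratio outcomes, each its own FDR family."""
    results = []
    for family, col in (
        ("head", "head_length_mm"),
        ("total", "total_length_mm"),
        ("ratio", "head_to_total_ratio_pct"),
    ):
        results += _run_tests(col, family, lengths.set_index("case_id")[col], covariates)
    return adjust_within_families(results)


def border_statistics(border: pd.DataFrame, covariates: pd.DataFrame) -> list[StatResult]:
    """Offset-by-reference border outcomes, FDR per offset-reference family."""
    results = []
    for off in sorted(border["offset_mm"].unique()):
        sub = border[border["offset_mm"] == off].set_index("case_id")
        for ref, col in (("full", "pct_of_full_width"), ("dg", "pct_of_dg_width")):
            family = f"border_{off:g}mm_{ref}"
            results += _run_tests(col, family, sub[col], covariates)
    return adjust_within_families(results)


def stats_to_frame(results: list[StatResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results])
    return df.sort_values(["family", "outcome", "covariate"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _length_rows(measured: list[dict]) -> pd.DataFrame:
    rows = []
    for m in measured:
        rec = m.get("lengths")
        rows.append(
            {
                "case_id": m["case_id"],
                "head_length_mm": None if rec is None else rec.head_length_mm,
                "total_length_mm": None if rec is None else rec.total_length_mm,
                "head_to_total_ratio_pct": None if rec is None else rec.head_to_total_ratio_pct,
            }
        )
    return pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)


def _border_rows(measured: list[dict]) -> pd.DataFrame:
    rows = []
    for m in measured:
        for off, bm in (m.get("border") or {}).items():
            if bm is None:
                continue
            rows.append(
                {
                    "case_id": m["case_id"],
                    "offset_mm": off,
                    "z": bm.z,
                    "pct_of_full_width": bm.pct_of_full_width,
                    "pct_of_dg_width": bm.pct_of_dg_width,
                }
            )
    return pd.DataFrame(rows, columns=["case_id", "offset_mm", "z",
                                       "pct_of_full_width", "pct_of_dg_width"]
                        ).sort_values(["case_id", "offset_mm"]).reset_index(drop=True)


def _subicular_rows(measured: list[dict]) -> pd.DataFrame:
    rows = []
    for m in measured:
        for rec in m.get("subicular") or []:
            rows.append(
                {
                    "case_id": m["case_id"],
                    "position_pct": rec.position_pct,
                    "z": rec.z,
                    "pct_PaS": rec.pct.get("PaS"),
                    "pct_PrS": rec.pct.get("PrS"),
                    "pct_SUB": rec.pct.get("SUB"),
                }
            )
    return pd.DataFrame(rows, columns=["case_id", "position_pct", "z",
                                       "pct_PaS", "pct_PrS", "pct_SUB"]
                        ).sort_values(["case_id", "position_pct"]).reset_index(drop=True)


def _srlm_rows(measured: list[dict]) -> pd.DataFrame:
    rows = []
    for m in measured:
        for rec in m.get("srlm") or []:
            rows.append(
                {
                    "case_id": m["case_id"],
                    "position_pct": rec.position_pct,
                    "z": rec.z,
                    "prop_CA1": rec.prop["CA1"],
                    "prop_CA2": rec.prop["CA2"],
                    "prop_CA3": rec.prop["CA3"],
                    "n_srlm_total": rec.n_srlm_total,
                    "sub_border_lateral_case": rec.sub_border_lateral_case,
                }
            )
    cols = ["case_id", "position_pct", "z", "prop_CA1", "prop_CA2", "prop_CA3",
            "n_srlm_total", "sub_border_lateral_case"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["case_id", "position_pct"]).reset_index(drop=True)


def _digitation_rows(measured: list[dict]) -> pd.DataFrame:
    rows = []
    for m in measured:
        d = m.get("digitations")
        if not d:
            continue
        rows.append(
            {
                "case_id": m["case_id"],
                "z": d["z"],
                "n_digitations": d["n_digitations"],
                "relation": d["record"].relation,
                "position": d["record"].position,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "z", "n_digitations",
                                       "relation", "position"]
                        ).sort_values("case_id").reset_index(drop=True)


def assemble_reports(measured: list[dict], covariates: pd.DataFrame | None = None) -> dict:
    """Cohort tables (DataFrames) from per-case measurement dicts."""
    reports = {
        "lengths": _length_rows(measured),
        "border": _border_rows(measured),
        "subicular": _subicular_rows(measured),
        "srlm": _srlm_rows(measured),
        "digitations": _digitation_rows(measured),
        "qc": pd.DataFrame(
            [{"case_id": m["case_id"], "note": q} for m in measured for q in m["qc"]],
            columns=["case_id", "note"],
        ),
    }
    if covariates is not None:
        cov = covariates.set_index("case_id")
        if len(measured) < 2:
            warnings.warn("cohort too small for statistics; skipped", stacklevel=2)
        else:
            stats = length_statistics(reports["lengths"], cov)
            if len(reports["border"]):
                stats += border_statistics(reports["border"], cov)
            reports["stats"] = stats_to_frame(stats)
    return reports


def write_reports(reports: dict, out_dir) -> None:
    """Deterministic TSV output (fixed column order and float format)."""
    os.makedirs(out_dir, exist_ok=True)
    for name, df in reports.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False,
                  float_format="%.6g")


def run_cohort(manifest_path, covariates_path, out_dir, schema_path=None) -> dict:
    """End-to-end cohort run from a manifest TSV.

    Manifest columns: case_id, volume, landmarks, hemisphere and optional
    coverage (paths relative to the manifest's directory). Covariates TSV
    columns: case_id, dementia, sex, age, fixation_days, pmi_hours.
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = os.path.dirname(os.path.abspath(manifest_path))
    schema = SubfieldSchema.from_json(schema_path) if schema_path else SubfieldSchema()

    measured = []
    for _, row in manifest.iterrows():
        vol = load_label_volume(os.path.join(base, row["volume"]), schema, row["hemisphere"])
        lm = Landmarks.from_json(os.path.join(base, row["landmarks"]))
        cov = None
        if "coverage" in row and isinstance(row["coverage"], str) and row["coverage"]:
            cov = CoverageMask.from_tsv(os.path.join(base, row["coverage"]), vol.n_slices)
        measured.append(measure_case(str(row["case_id"]), vol, lm, cov))

    covariates = pd.read_csv(covariates_path, sep="\t") if covariates_path else None
    reports = assemble_reports(measured, covariates)
    write_reports(reports, out_dir)
    with open(os.path.join(out_dir, "qc.json"), "w") as fh:
        json.dump(
            {m["case_id"]: m["qc"] for m in measured}, fh, indent=1, sort_keys=True
        )
    return reports
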