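"""Full plan evaluation: generate fields, sum, compute metrics, report.

A plan is one or more fields (minibeam arrays or seamless broad beams) on a
common lattice.  Fields are generated individually (each normalised to
100% mean peak dose in the target band), the summed plan is the mean of
the field doses (each field delivers an equal share of the prescription),
and all dose metrics are computed on the summed grid *after* summation —
summing first is what produces the multi-field homogenisation effect
(summed s-index below the individual-field s-indices).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dvh as _dvh
from . import fractionation as _frac
from .gamma import GammaCriteria, gamma_index, passing_rate
from .grids import Quantity, StructureMask, VoxelGrid, build_box_mask
from .let_rbe import RBEParams, rbe_weighted_dose
from .synthetic import (
    ConfigError,
    GridSpec,
    MinibeamPlanConfig,
    generate_pmbrt_dose,
    generate_seamless_dose,
)


@dataclasses.dataclass
class FieldSpec:
    """One field of a plan: a generator config plus delivery technique."""

    config: MinibeamPlanConfig
    technique: str = "pmbrt"  # 'pmbrt' or 'seamless'

    def __post_init__(self) -> None:
        if self.technique not in ("pmbrt", "seamless"):
            raise ConfigError("technique must be 'pmbrt' or 'seamless'")


@dataclasses.dataclass
class PlanSpec:
    """Declarative description of a full plan evaluation."""

    name: str
    fields: list[FieldSpec]
    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    ptv: tuple | None = None          # (lower, upper) mm box
    organs: dict = dataclasses.field(default_factory=dict)
    depths: list = dataclasses.field(default_factory=list)
    rbe: RBEParams | None = None
    gamma_reference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fields:
            raise ConfigError("a plan needs at least one field")

    @classmethod
    def from_dict(cls, data: dict) -> "PlanSpec":
        fields = []
        for entry in data.get("fields", []):
            cfg = entry.get("config")
            if isinstance(cfg, str):
                config = MinibeamPlanConfig.bundled(cfg)
            else:
                config = MinibeamPlanConfig.from_dict(dict(cfg or {}))
            overrides = entry.get("overrides") or {}
            if overrides:
                config = dataclasses.replace(config, **overrides)
            fields.append(FieldSpec(config, entry.get("technique", "pmbrt")))
        grid = GridSpec.from_dict(data["grid"]) if "grid" in data else GridSpec()
        ptv = None
        if data.get("ptv"):
            ptv = (tuple(data["ptv"]["lower"]), tuple(data["ptv"]["upper"]))
        organs = {
            name: (tuple(box["lower"]), tuple(box["upper"]))
            for name, box in (data.get("organs") or {}).items()
        }
        rbe = RBEParams(**data["rbe"]) if data.get("rbe") else None
        return cls(
            name=data.get("name", "plan"),
            fields=fields,
            grid=grid,
            ptv=ptv,
            organs=organs,
            depths=list(data.get("depths") or []),
            rbe=rbe,
            gamma_reference=bool(data.get("gamma_reference", False)),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlanSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def bundled(cls, name: str) -> "PlanSpec":
        from importlib import resources

        ref = resources.files("pmbrt") / "configs" / f"{name}.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def _field_seed(master: int, key: object) -> int:
    """Stable per-field seed from the master seed and the field config.

    Derived from the config content (not the field position) so that
    permuting the field list leaves every generated grid — and hence all
    summed-plan metrics — unchanged.
    """
    if dataclasses.is_dataclass(key) and not isinstance(key, type):
        key = dataclasses.asdict(key)
    blob = json.dumps([int(master), key], sort_keys=True, default=str)
    return zlib.crc32(blob.encode()) % (2**31)


def _structure_report(dose: VoxelGrid, mask: StructureMask,
                      ctc: float | None) -> dict:
    rep = _dvh.coverage_stats(dose, mask)
    out = rep.as_dict()
    if ctc is not None:
        try:
            ps = _frac.pvdr_per_organ(dose, mask, ctc=ctc)
            out["pvdr"] = ps.pvdr_mean
            out["pvdr_sd"] = ps.pvdr_sd
            out["n_peaks"] = ps.n_peaks
        except _frac.InsufficientExtentError:
            out["pvdr"] = None
    return out


def _depth_table(dose: VoxelGrid, depths, slab_voxels: int = 3) -> list[dict]:
    rows = []
    for depth in depths:
        ps = _frac.pvdr_at_depth(dose, depth, slab_voxels=slab_voxels,
                                 interior_only=True)
        rows.append({
            "depth_mm": float(depth),
            "fwhm_mm": None if np.isnan(ps.fwhm) else round(float(ps.fwhm), 3),
            "pvdr_mean": round(float(ps.pvdr_mean), 3),
            "pvdr_sd": round(float(ps.pvdr_sd), 3),
            "valley_dose_pct": (None if np.isnan(ps.valley_dose)
                                else round(float(ps.valley_dose), 3)),
            "no_fractionation": ps.no_fractionation,
        })
    return rows


def evaluate_plan(spec: PlanSpec, outdir: str | Path | None = None,
                  seed: int | None = None) -> dict:
    """Evaluate a plan and return (and optionally write) the report.

    Deterministic under a fixed seed: the report dictionary (and the JSON
    serialisation) is byte-identical across reruns.
    """
    master = spec.seed if seed is None else int(seed)
    field_doses: list[VoxelGrid] = []
    field_lets: list[VoxelGrid | None] = []
    for field in spec.fields:
        cfg = field.config
        if cfg.seed is None:
            cfg = dataclasses.replace(cfg, seed=_field_seed(master, cfg))
        if field.technique == "pmbrt":
            dose_grid, let_grid = generate_pmbrt_dose(cfg, spec.grid)
        else:
            dose_grid = generate_seamless_dose(cfg, spec.grid)
            let_grid = None
        field_doses.append(dose_grid)
        field_lets.append(let_grid)

    # summed plan: mean of field doses (equal prescription share per field)
    summed_values = np.mean([g.values for g in field_doses], axis=0)
    summed = VoxelGrid(summed_values, spec.grid.spacing, spec.grid.origin,
                       Quantity.DOSE)

    # dose-averaged LET of the summed plan
    summed_let = None
    pm = [(d, l) for d, l in zip(field_doses, field_lets) if l is not None]
    if pm:
        num = sum(d.values * l.values for d, l in pm)
        den = sum(d.values for d, _ in pm)
        let_vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        summed_let = VoxelGrid(let_vals, spec.grid.spacing, spec.grid.origin,
                               Quantity.LET)

    ptv_mask = None
    if spec.ptv is not None:
        ptv_mask = build_box_mask(summed, "PTV", spec.ptv[0], spec.ptv[1])

    report: dict = {"plan": spec.name, "seed": master,
                    "n_fields": len(spec.fields)}

    per_field = []
    for i, (field, dose_grid) in enumerate(zip(spec.fields, field_doses)):
        entry: dict = {"field": i + 1, "technique": field.technique,
                       "name": field.config.name or f"field_{i + 1}"}
        if ptv_mask is not None:
            ctc = field.config.ctc if field.technique == "pmbrt" else None
            entry["ptv"] = _structure_report(dose_grid, ptv_mask, ctc)
        per_field.append(entry)
    report["per_field"] = per_field

    summed_entry: dict = {}
    ctc0 = next((f.config.ctc for f in spec.fields if f.technique == "pmbrt"),
                None)
    if ptv_mask is not None:
        summed_entry["ptv"] = _structure_report(summed, ptv_mask, ctc0)
    organs_entry = {}
    for organ, (lo, hi) in spec.organs.items():
        mask = build_box_mask(summed, organ, lo, hi)
        organs_entry[organ] = _structure_report(summed, mask, ctc0)
    if organs_entry:
        summed_entry["organs"] = organs_entry
    report["summed"] = summed_entry

    # Table-4-style depth metrics on the first minibeam field
    first_pmbrt = next((d for f, d in zip(spec.fields, field_doses)
                        if f.technique == "pmbrt"), None)
    if spec.depths and first_pmbrt is not None:
        report["depth_table"] = _depth_table(first_pmbrt, spec.depths)

    # RBE-weighted dose statistics on the summed plan
    if spec.rbe is not None and summed_let is not None and ptv_mask is not None:
        normal = StructureMask("normal", ~ptv_mask.mask, spec.grid.spacing,
                               spec.grid.origin)
        res = rbe_weighted_dose(summed, summed_let, spec.rbe,
                                ptv_mask, normal)
        in_field = summed.values > 0.1 * summed.values.max()
        report["rbe"] = {
            "model": spec.rbe.model.value,
            "dose_per_fraction_gy": spec.rbe.dose_per_fraction,
            "mean_rbe_ptv": round(float(res.rbe.values[ptv_mask.mask].mean()), 4),
            "mean_rbe_normal_infield": round(
                float(res.rbe.values[normal.mask & in_field].mean()), 4),
            "mean_rbe_weighted_dose_ptv": round(
                float(res.weighted.values[ptv_mask.mask].mean()), 3),
            "n_undefined_let": res.n_undefined,
        }

    # TPS-vs-MC style gamma check on the seamless comparison arm
    if spec.gamma_reference:
        cfg0 = spec.fields[0].config
        tps = generate_seamless_dose(
            dataclasses.replace(cfg0, noise_rel=0.0, seed=None), spec.grid)
        mc = generate_seamless_dose(
            dataclasses.replace(cfg0, seed=_field_seed(master, "gamma-mc")),
            spec.grid)
        criteria = GammaCriteria(dose_tol=0.03, dta=3.0, mode="local")
        gam = gamma_index(tps, mc, criteria)
        report["gamma"] = {
            "criteria": "3%/3mm local",
            "passing_rate_pct": round(passing_rate(gam), 2),
            "n_evaluated": int(np.isfinite(gam.values).sum()),
        }

    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = []
    for entry in report.get("per_field", []):
        if "ptv" in entry:
            rows.append({"structure": "PTV", "field": entry["field"],
                         **entry["ptv"]})
    summed = report.get("summed", {})
    if "ptv" in summed:
        rows.append({"structure": "PTV", "field": "summed", **summed["ptv"]})
    for organ, stats in summed.get("organs", {}).items():
        rows.append({"structure": organ, "field": "summed", **stats})
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "structures.csv", index=False)
    if "depth_table" in report:
        pd.DataFrame(report["depth_table"]).to_csv(
            outdir / "depth_metrics.csv", index=False)
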