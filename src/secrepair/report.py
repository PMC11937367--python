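"""Run configuration, input validation and the combined run report.

A run is described by one YAML/dict config with a single master seed;
every module draws from a deterministic per-module substream so stages can
be rerun independently yet reproduce the joint run. Identical config +
inputs + seed yields an identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from ._util import child_seed
from .funnel import SecretomeFunnel
from .histology import lmi, lmi_per_animal, ihc_quantify
from .organoids import OrganoidAssay
from .simulate import (
    HistologyFixtureConfig,
    OrganoidFixtureConfig,
    SecretomeFixtureConfig,
    generate_alveolar_mask,
    generate_ihc_image,
    generate_organoid_experiment,
    generate_secretome_fixture,
)
from . import io as sio

__all__ = ["RunConfig", "validate_inputs", "run_all", "simulate_fixtures"]

_KNOWN_KEYS = {"seed", "output_dir", "simulate", "funnel", "organoids",
               "histology"}


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys rejected)."""

    seed: int = 0
    output_dir: str = "secrepair_out"
    simulate: dict[str, Any] | None = None
    funnel: dict[str, Any] | None = None
    organoids: dict[str, Any] | None = None
    histology: dict[str, Any] | None = None
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "secrepair_out")),
            simulate=d.get("simulate"),
            funnel=d.get("funnel"),
            organoids=d.get("organoids"),
            histology=d.get("histology"),
            raw=dict(d),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError("config must be a YAML mapping")
        return cls.from_dict(d)


def validate_inputs(config: RunConfig) -> list[dict]:
    """Check declared input files; report (never raise) problems."""
    findings: list[dict] = []

    def check_file(stage: str, key: str, path: Any):
        if path is None:
            findings.append(
                {"stage": stage, "severity": "error",
                 "message": f"missing required path {key!r}"}
            )
        elif not Path(str(path)).exists():
            findings.append(
                {"stage": stage, "severity": "error",
                 "message": f"{key} file not found: {path}"}
            )

    if config.funnel:
        for key in ("detections", "gmt", "secretion", "lr", "expression"):
            check_file("funnel", key, config.funnel.get(key))
        det = config.funnel.get("detections")
        if det and Path(str(det)).exists():
            try:
                table = sio.read_detection_table(det)
                if (table.frame["replicate"] < 1).any():
                    findings.append(
                        {"stage": "funnel", "severity": "error",
                         "message": "negative or zero replicate index"}
                    )
            except Exception as exc:  # noqa: BLE001 - reported, not raised
                findings.append(
                    {"stage": "funnel", "severity": "error",
                     "message": f"detection table invalid: {exc}"}
                )
    if config.organoids:
        check_file("organoids", "counts", config.organoids.get("counts"))
    if config.histology:
        for entry in config.histology.get("ihc_images", []):
            check_file("histology", "image", entry.get("path"))
        for entry in config.histology.get("lmi_masks", []):
            check_file("histology", "mask", entry.get("path"))
    return findings


def simulate_fixtures(
    params: dict[str, Any], seed: int, outdir: Path
) -> dict[str, Any]:
    """Generate the requested fixture families into ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Any] = {}
    if "secretome" in params:
        cfg = SecretomeFixtureConfig(
            **{**params["secretome"], "seed": child_seed(seed, "secretome")}
        )
        table, bundle, truth = generate_secretome_fixture(cfg)
        sio.write_detection_table(table, outdir / "detections.tsv")
        paths = sio.write_annotation_bundle(bundle, outdir)
        sio.write_truth(truth, outdir / "secretome_truth.json")
        produced["secretome"] = {
            "detections": str(outdir / "detections.tsv"),
            **paths,
            "truth": str(outdir / "secretome_truth.json"),
        }
    if "organoids" in params:
        cfg = OrganoidFixtureConfig(
            **{**params["organoids"], "seed": child_seed(seed, "organoids")}
        )
        experiments, truth = generate_organoid_experiment(cfg)
        sio.write_organoid_tables(
            experiments, outdir / "organoid_counts.tsv",
            outdir / "organoid_diameters.tsv",
        )
        sio.write_truth(truth, outdir / "organoid_truth.json")
        produced["organoids"] = {
            "counts": str(outdir / "organoid_counts.tsv"),
            "diameters": str(outdir / "organoid_diameters.tsv"),
            "truth": str(outdir / "organoid_truth.json"),
        }
    if "ihc" in params:
        cfg = HistologyFixtureConfig(
            **{**params["ihc"], "seed": child_seed(seed, "ihc")}
        )
        image, truth = generate_ihc_image(cfg)
        sio.write_stain_image(image, outdir / "ihc_field.tif")
        sio.write_truth(truth, outdir / "ihc_truth.json")
        produced["ihc"] = {
            "image": str(outdir / "ihc_field.tif"),
            "pixel_size": cfg.pixel_size,
            "truth": str(outdir / "ihc_truth.json"),
        }
    if "alveolar_mask" in params:
        cfg = HistologyFixtureConfig(
            **{**params["alveolar_mask"], "seed": child_seed(seed, "mask")}
        )
        mask, truth = generate_alveolar_mask(cfg)
        sio.write_mask(mask, outdir / "alveolar_mask.png")
        sio.write_truth(truth, outdir / "mask_truth.json")
        produced["alveolar_mask"] = {
            "mask": str(outdir / "alveolar_mask.png"),
            "pixel_size": cfg.pixel_size,
            "truth": str(outdir / "mask_truth.json"),
        }
    return produced


def run_all(config: RunConfig, write: bool = True) -> dict:
    """Execute the requested stages in dependency order; return the report."""
    outdir = Path(config.output_dir)
    report: dict[str, Any] = {
        "tool": "secrepair",
        "version": __version__,
        "config": config.raw,
        "results": {},
        "warnings": [],
    }
    if config.simulate is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        report["results"]["simulate"] = simulate_fixtures(
            config.simulate, config.seed, outdir / "fixtures"
        )
    if config.funnel is not None:
        fc = dict(config.funnel)
        table = sio.read_detection_table(fc["detections"])
        bundle = sio.read_annotation_bundle(
            fc["gmt"], fc["secretion"], fc["lr"], fc["expression"]
        )
        result = SecretomeFunnel(
            table, bundle, secretion_mode=fc.get("secretion_mode", "any")
        ).run()
        report["results"]["funnel"] = result.to_dict()
    if config.organoids is not None:
        oc = dict(config.organoids)
        experiments = sio.read_organoid_tables(
            oc["counts"], oc.get("diameters")
        )
        assay = OrganoidAssay(
            experiments,
            control=oc.get("control", "control"),
            paired=bool(oc.get("paired", False)),
            seed=child_seed(config.seed, "bootstrap"),
        )
        report["results"]["organoids"] = assay.fit().to_dict()
    if config.histology is not None:
        hc = dict(config.histology)
        ihc_results = []
        for entry in hc.get("ihc_images", []):
            image = sio.read_stain_image(
                entry["path"], pixel_size=entry.get("pixel_size")
            )
            q = ihc_quantify(image, threshold=entry.get("threshold", "otsu"))
            ihc_results.append({"image": str(entry["path"]), **q.to_dict()})
        lmi_results = []
        fields = []
        for entry in hc.get("lmi_masks", []):
            mask = sio.read_mask(entry["path"])
            res = lmi(
                mask,
                pixel_size=float(entry.get("pixel_size", 1.0)),
                line_spacing=float(entry.get("line_spacing", 1.0)),
                orientation=entry.get("orientation", "both"),
            )
            fields.append(res)
            lmi_results.append({"mask": str(entry["path"]), **res.to_dict()})
        hist: dict[str, Any] = {}
        if ihc_results:
            hist["ihc"] = ihc_results
        if lmi_results:
            hist["lmi_fields"] = lmi_results
            if len(fields) > 1:
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    hist["lmi_overall"] = lmi_per_animal(fields).to_dict()
        report["results"]["histology"] = hist
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
    return report
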