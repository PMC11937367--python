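"""Readers and writers for the plain-text interchange formats.

Detection tables and organoid tables travel as TSV, gene sets as GMT,
ligand–receptor pairs / secretion calls / receptor-expression flags as
TSV, fixture truth as JSON, stain images as 8-bit RGB TIFF and binary
masks as 8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .funnel import AnnotationBundle, DetectionTable
from .histology import BinaryMask, StainImage
from .organoids import TYPE_CATEGORIES, OrganoidExperiment
from .simulate import FixtureTruth

__all__ = [
    "read_detection_table",
    "write_detection_table",
    "read_gmt",
    "write_gmt",
    "read_secretion_calls",
    "write_secretion_calls",
    "read_ligand_receptor_pairs",
    "write_ligand_receptor_pairs",
    "read_receptor_expression",
    "write_receptor_expression",
    "read_annotation_bundle",
    "write_annotation_bundle",
    "read_organoid_tables",
    "write_organoid_tables",
    "read_truth",
    "write_truth",
    "read_stain_image",
    "write_stain_image",
    "read_mask",
    "write_mask",
]


def read_detection_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    intensity_threshold: float = 0.0,
) -> DetectionTable:
    """Read a detection TSV/CSV; intensity columns are binarized at > threshold."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return DetectionTable.from_dataframe(
        df, dialect=dialect, intensity_threshold=intensity_threshold
    )


def write_detection_table(table: DetectionTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["detected"] = df["detected"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    if not sets:
        raise ValueError(f"GMT file {path} contains no gene sets")
    return sets


def write_gmt(gene_sets: Mapping[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name, *sorted(genes)])
        for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_secretion_calls(path: str | Path) -> dict[str, dict[str, bool]]:
    """TSV: gene_symbol + one boolean column per predictor."""
    df = pd.read_csv(path, sep="\t")
    if "gene_symbol" not in df.columns or len(df.columns) < 2:
        raise ValueError("secretion calls need gene_symbol + predictor columns")
    predictors = [c for c in df.columns if c != "gene_symbol"]
    return {
        str(row["gene_symbol"]).upper(): {
            p: bool(int(row[p])) for p in predictors
        }
        for _, row in df.iterrows()
    }


def write_secretion_calls(
    calls: Mapping[str, Mapping[str, bool]], path: str | Path
) -> None:
    predictors = sorted({p for c in calls.values() for p in c})
    rows = [
        {"gene_symbol": g, **{p: int(c.get(p, False)) for p in predictors}}
        for g, c in sorted(calls.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ligand_receptor_pairs(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError("ligand-receptor TSV needs 'ligand' and 'receptor'")
    return {
        (str(l).upper(), str(r).upper())
        for l, r in zip(df["ligand"], df["receptor"])
    }


def write_ligand_receptor_pairs(
    pairs: set[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(sorted(pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


def read_receptor_expression(path: str | Path) -> dict[tuple[str, str], bool]:
    df = pd.read_csv(path, sep="\t")
    for col in ("receptor", "cell_type", "expressed"):
        if col not in df.columns:
            raise ValueError(
                "receptor expression TSV needs receptor, cell_type, expressed"
            )
    return {
        (str(r).upper(), str(c).upper()): bool(int(e))
        for r, c, e in zip(df["receptor"], df["cell_type"], df["expressed"])
    }


def write_receptor_expression(
    expression: Mapping[tuple[str, str], bool], path: str | Path
) -> None:
    rows = [
        {"receptor": r, "cell_type": c, "expressed": int(v)}
        for (r, c), v in sorted(expression.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_bundle(
    gmt_path: str | Path,
    secretion_path: str | Path,
    lr_path: str | Path,
    expression_path: str | Path,
    target_cell_types: set[str] | None = None,
) -> AnnotationBundle:
    gene_sets = read_gmt(gmt_path)
    merged: set[str] = set()
    for genes in gene_sets.values():
        merged |= genes
    expression = read_receptor_expression(expression_path)
    cells = target_cell_types or {c for (_, c) in expression} or {"AT1", "AT2"}
    return AnnotationBundle(
        growth_factor_cytokine_set=merged,
        secretion_calls=read_secretion_calls(secretion_path),
        ligand_receptor_pairs=read_ligand_receptor_pairs(lr_path),
        receptor_expression=expression,
        target_cell_types=cells,
    )


def write_annotation_bundle(bundle: AnnotationBundle, outdir: str | Path) -> dict:
    """Write all bundle components into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": outdir / "growth_factors.gmt",
        "secretion": outdir / "secretion_calls.tsv",
        "lr": outdir / "ligand_receptor_pairs.tsv",
        "expression": outdir / "receptor_expression.tsv",
    }
    write_gmt(
        {"GROWTH_FACTORS_CYTOKINES": bundle.growth_factor_cytokine_set},
        paths["gmt"],
    )
    write_secretion_calls(bundle.secretion_calls, paths["secretion"])
    write_ligand_receptor_pairs(bundle.ligand_receptor_pairs, paths["lr"])
    write_receptor_expression(bundle.receptor_expression, paths["expression"])
    return {k: str(v) for k, v in paths.items()}


def write_organoid_tables(
    experiments: list[OrganoidExperiment],
    counts_path: str | Path,
    diameters_path: str | Path,
) -> None:
    counts_rows, diam_rows = [], []
    for e in experiments:
        row = {
            "condition": e.condition,
            "replicate_id": e.replicate_id,
            "n_seeded": e.n_seeded,
            "n_organoids": e.n_organoids,
        }
        for cat in TYPE_CATEGORIES:
            if cat in e.type_counts:
                row[cat] = e.type_counts[cat]
        counts_rows.append(row)
        diam_rows.extend(
            {
                "condition": e.condition,
                "replicate_id": e.replicate_id,
                "diameter_um": d,
            }
            for d in e.diameters
        )
    pd.DataFrame(counts_rows).to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(
        diam_rows, columns=["condition", "replicate_id", "diameter_um"]
    ).to_csv(diameters_path, sep="\t", index=False)


def read_organoid_tables(
    counts_path: str | Path, diameters_path: str | Path | None = None
) -> list[OrganoidExperiment]:
    counts = pd.read_csv(counts_path, sep="\t")
    diams = (
        pd.read_csv(diameters_path, sep="\t") if diameters_path else None
    )
    experiments = []
    for _, row in counts.iterrows():
        tc = {
            c: int(row[c])
            for c in TYPE_CATEGORIES
            if c in counts.columns and not pd.isna(row[c])
        }
        dlist: list[float] = []
        if diams is not None:
            sel = diams[
                (diams["condition"] == row["condition"])
                & (diams["replicate_id"].astype(str) == str(row["replicate_id"]))
            ]
            dlist = sel["diameter_um"].astype(float).tolist()
        experiments.append(
            OrganoidExperiment(
                condition=str(row["condition"]),
                replicate_id=str(row["replicate_id"]),
                n_seeded=int(row["n_seeded"]),
                n_organoids=int(row["n_organoids"]),
                diameters=dlist,
                type_counts=tc,
            )
        )
    return experiments


def write_truth(truth: FixtureTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path: str | Path) -> FixtureTruth:
    d = json.loads(Path(path).read_text())
    return FixtureTruth(
        expected_candidate_set=(
            set(d["expected_candidate_set"])
            if d.get("expected_candidate_set") is not None
            else None
        ),
        expected_stage_counts=d.get("expected_stage_counts"),
        planted_effect_ratio=d.get("planted_effect_ratio"),
        planted_positive_fraction=d.get("planted_positive_fraction"),
        planted_mean_chord=d.get("planted_mean_chord"),
        extras=d.get("extras", {}),
    )


def write_stain_image(image: StainImage, path: str | Path) -> None:
    """8-bit RGB TIFF with the pixel size recorded in the resolution tags."""
    px_per_um = 1.0 / image.pixel_size
    tifffile.imwrite(
        str(path),
        image.pixels,
        photometric="rgb",
        resolution=(px_per_um, px_per_um),
        resolutionunit="NONE",
        metadata={"pixel_size_um": image.pixel_size, "field_id": image.field_id},
    )


def read_stain_image(path: str | Path, pixel_size: float | None = None) -> StainImage:
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        if pixel_size is None:
            meta = tf.shaped_metadata
            if meta and "pixel_size_um" in meta[0]:
                pixel_size = float(meta[0]["pixel_size_um"])
            else:
                raise ValueError(
                    "pixel size not stored in file; pass pixel_size explicitly"
                )
    return StainImage(pixels, pixel_size=pixel_size, field_id=Path(path).stem)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Binary mask as an 8-bit PNG (255 = True)."""
    Image.fromarray((mask.mask.astype(np.uint8) * 255), mode="L").save(path)


def read_mask(path: str | Path, semantics: str = "airspace") -> BinaryMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(arr > 127, semantics=semantics)
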