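"""Synthetic fixtures with planted, bookkept ground truth.

Three generator families emulate the study's data structures at desk scale:

* secretome detection tables (protein x replicate x EV/SF fraction, four
  replicates by default) with an annotation bundle and a planted candidate
  set that the prioritization funnel must recover exactly;
* paired organoid assay outcomes (binomial colony formation out of seeded
  cells, truncated-lognormal diameters, immunostaining type counts);
* stained-section images (forward optical-density stain mixing with a
  planted positive fraction) and binary airspace masks (band or disk
  geometry with an analytically known mean chord) for the histology
  quantifiers.

Every expected value in :class:`FixtureTruth` is recorded by direct
bookkeeping while the fixture is generated, never re-derived from the
generated data afterwards. Identical (config, seed) gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import EV, SF
from .funnel import AnnotationBundle, DetectionTable
from .histology import DEFAULT_STAIN_VECTORS, BinaryMask, StainImage
from .organoids import TYPE_CATEGORIES, OrganoidExperiment

__all__ = [
    "SecretomeFixtureConfig",
    "OrganoidFixtureConfig",
    "HistologyFixtureConfig",
    "FixtureTruth",
    "generate_secretome_fixture",
    "generate_organoid_experiment",
    "generate_ihc_image",
    "generate_alveolar_mask",
]


@dataclass
class FixtureTruth:
    """Planted ground truth, recorded at generation time."""

    expected_candidate_set: set[str] | None = None
    expected_stage_counts: dict | None = None
    planted_effect_ratio: float | None = None
    planted_positive_fraction: float | None = None
    planted_mean_chord: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "expected_candidate_set": (
                sorted(self.expected_candidate_set)
                if self.expected_candidate_set is not None
                else None
            ),
            "expected_stage_counts": self.expected_stage_counts,
            "planted_effect_ratio": self.planted_effect_ratio,
            "planted_positive_fraction": self.planted_positive_fraction,
            "planted_mean_chord": self.planted_mean_chord,
            "extras": self.extras,
        }


# ---------------------------------------------------------------------------
# secretome fixture


@dataclass
class SecretomeFixtureConfig:
    """Configuration of a synthetic paired EV / soluble-fraction proteome.

    ``frac_consistent_ev`` / ``frac_consistent_sf`` are the marginal
    probabilities that a decoy protein is detected in all replicates of the
    respective fraction. ``detection_noise`` is the per-replicate dropout
    probability applied to consistent decoy proteins (planted candidates
    are exempt so the planted truth stays exact).
    """

    n_proteins: int = 200
    n_replicates: int = 4
    frac_consistent_ev: float = 0.25
    frac_consistent_sf: float = 0.60
    n_planted_candidates: int = 5
    detection_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be >= 1")
        if self.n_planted_candidates > self.n_proteins:
            raise ValueError("n_planted_candidates exceeds n_proteins")
        if self.n_planted_candidates < 0:
            raise ValueError("n_planted_candidates must be >= 0")
        for name in ("frac_consistent_ev", "frac_consistent_sf",
                     "detection_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


_PLANT_PROVENANCE = ("both", "SF_only", "EV_only")
_PLANT_PROVENANCE_P = (0.45, 0.40, 0.15)


def generate_secretome_fixture(
    config: SecretomeFixtureConfig,
) -> tuple[DetectionTable, AnnotationBundle, FixtureTruth]:
    """Generate a detection table + annotation bundle with planted candidates.

    Planted candidates are consistent in their assigned compartment(s),
    annotated as growth factors, predicted secreted, and paired to a
    receptor expressed in a target cell type. Decoy proteins are constructed
    to fail at controlled stages (inconsistent detection; consistent but not
    a growth factor; growth factor but not secreted; secreted but without an
    expressed receptor), so the funnel's output equals the planted set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, r = config.n_proteins, config.n_replicates

    genes = [f"GENE{i:04d}" for i in range(1, n + 1)]
    prots = [f"P{i:05d}" for i in range(1, n + 1)]
    planted_idx = set(
        rng.choice(n, size=config.n_planted_candidates, replace=False).tolist()
    )

    # bookkeeping sets, updated as each protein's detections are decided
    identified = {EV: set(), SF: set()}
    consistent = {EV: set(), SF: set()}

    def partial_detect(j: int) -> np.ndarray:
        """Detection flags for exactly j of r replicates (j < r)."""
        flags = np.zeros(r, dtype=bool)
        if j > 0:
            flags[rng.choice(r, size=j, replace=False)] = True
        return flags

    rows: list[dict] = []
    plant_prov: dict[str, str] = {}
    for i in range(n):
        gene, prot = genes[i], prots[i]
        if i in planted_idx:
            prov = rng.choice(_PLANT_PROVENANCE, p=_PLANT_PROVENANCE_P)
            plant_prov[gene] = str(prov)
            cons = {
                EV: prov in ("both", "EV_only"),
                SF: prov in ("both", "SF_only"),
            }
        else:
            cons = {
                EV: bool(rng.random() < config.frac_consistent_ev),
                SF: bool(rng.random() < config.frac_consistent_sf),
            }
        flags = {}
        for frac in (EV, SF):
            if cons[frac]:
                det = np.ones(r, dtype=bool)
                if i not in planted_idx and config.detection_noise > 0:
                    drop = rng.random(r) < config.detection_noise
                    det &= ~drop
                    cons[frac] = bool(det.all())
            else:
                det = partial_detect(int(rng.integers(0, r)))
            flags[frac] = det
        if not (flags[EV].any() or flags[SF].any()):
            # every protein is identified somewhere at least once
            frac = EV if rng.random() < 0.5 else SF
            flags[frac] = partial_detect(int(rng.integers(1, r)) if r > 1 else 1)
        for frac in (EV, SF):
            if flags[frac].any():
                identified[frac].add(gene)
            if flags[frac].all():
                consistent[frac].add(gene)
            for rep in range(r):
                rows.append(
                    {
                        "protein_id": prot,
                        "gene_symbol": gene,
                        "fraction": frac,
                        "replicate": rep + 1,
                        "detected": bool(flags[frac][rep]),
                    }
                )

    planted_genes = {genes[i] for i in planted_idx}
    # noise may have demoted a planted compartment only if it applied to
    # planted proteins — it does not; assert the invariant all the same
    assert all(
        g in consistent[EV] or g in consistent[SF] for g in planted_genes
    )

    union = consistent[EV] | consistent[SF]
    venn = {
        "EV_only": consistent[EV] - consistent[SF],
        "SF_only": consistent[SF] - consistent[EV],
        "both": consistent[EV] & consistent[SF],
    }

    # annotation fates for consistent decoys
    gf_set: set[str] = set(planted_genes)
    secretion_calls: dict[str, dict[str, bool]] = {}
    lr_pairs: set[tuple[str, str]] = set()
    expression: dict[tuple[str, str], bool] = {}
    secreted: set[str] = set(planted_genes)
    receptor_matched: set[str] = set(planted_genes)

    for gene in sorted(planted_genes):
        secretion_calls[gene] = {
            "SignalP": True,
            "Phobius": bool(rng.random() < 0.7),
        }
        receptor = f"{gene}R"
        lr_pairs.add((gene, receptor))
        cells = ["AT1", "AT2"]
        expressed_in = rng.choice([0, 1, 2], p=[0.3, 0.3, 0.4])
        if expressed_in == 2:
            chosen = cells
        else:
            chosen = [cells[int(expressed_in)]]
        for cell in cells:
            expression[(receptor, cell)] = cell in chosen

    for gene in sorted(union - planted_genes):
        u = rng.random()
        if u >= 0.35:
            continue  # consistent but not a growth factor
        gf_set.add(gene)
        if rng.random() < 0.4:
            # growth factor, predicted non-secreted
            secretion_calls[gene] = {"SignalP": False, "Phobius": False}
            continue
        secretion_calls[gene] = {
            "SignalP": bool(rng.random() < 0.8),
            "Phobius": True,
        }
        secreted.add(gene)
        if rng.random() < 0.5:
            continue  # secreted but no known receptor
        receptor = f"{gene}R"
        lr_pairs.add((gene, receptor))
        expression[(receptor, "AT1")] = False
        expression[(receptor, "AT2")] = False

    # pad the gene set with symbols absent from the table (realistic GMT)
    gf_set |= {f"EXTRA{i:03d}" for i in range(1, 11)}

    table = DetectionTable(pd.DataFrame(rows))
    bundle = AnnotationBundle(
        growth_factor_cytokine_set=gf_set,
        secretion_calls=secretion_calls,
        ligand_receptor_pairs=lr_pairs,
        receptor_expression=expression,
        target_cell_types={"AT1", "AT2"},
    )

    gf_in_table = gf_set & union
    stage_counts = {
        "identified": {EV: len(identified[EV]), SF: len(identified[SF])},
        "consistent": {EV: len(consistent[EV]), SF: len(consistent[SF])},
        "venn": {k: len(v) for k, v in venn.items()},
        "growth_factor": len(gf_in_table),
        "secreted": len(secreted),
        "receptor_matched": len(receptor_matched),
    }
    truth = FixtureTruth(
        expected_candidate_set=set(planted_genes),
        expected_stage_counts=stage_counts,
        extras={"planted_provenance": plant_prov},
    )
    return table, bundle, truth


# ---------------------------------------------------------------------------
# organoid fixture


@dataclass
class OrganoidFixtureConfig:
    """Paired organoid assay generator settings.

    The default treatment effect (``treatment_cfe_ratio = 1.75``) is the
    calibrated lead-candidate effect: roughly 75% more organoids than
    paired controls. ``cse_cfe_ratio`` (< 1) models cigarette-smoke-extract
    suppression with a mild diameter increase. Diameters are lognormal
    (sizes are right-skewed and displayed on a log scale) truncated at the
    50 µm counting threshold.
    """

    n_seeded: int = 10_000
    baseline_cfe: float = 0.01
    treatment_cfe_ratio: float = 1.75
    cse_cfe_ratio: float = 0.6
    diameter_log_mean: float = math.log(120.0)
    diameter_log_sd: float = 0.4
    cse_diameter_log_shift: float = 0.15
    n_replicates: int = 8
    include_cse: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_seeded < 1 or self.n_replicates < 1:
            raise ValueError("n_seeded and n_replicates must be >= 1")
        if not 0 < self.baseline_cfe <= 1:
            raise ValueError("baseline_cfe must be in (0, 1]")
        if self.treatment_cfe_ratio <= 0 or self.cse_cfe_ratio <= 0:
            raise ValueError("CFE ratios must be positive")
        if self.baseline_cfe * self.treatment_cfe_ratio > 1:
            raise ValueError("baseline_cfe * treatment_cfe_ratio exceeds 1")
        if not self.cse_cfe_ratio < 1:
            raise ValueError("cse_cfe_ratio must be < 1")
        if self.diameter_log_sd <= 0:
            raise ValueError("diameter_log_sd must be > 0")


_TYPE_PROPS = (0.55, 0.20, 0.15, 0.10)  # SPC+, ACT+, SPC+/ACT+, SPC-/ACT-


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lower: float
) -> list[float]:
    """Lognormal draws conditioned on exceeding ``lower`` (rejection)."""
    out: list[float] = []
    while len(out) < n:
        block = rng.lognormal(mu, sigma, size=max(4 * (n - len(out)), 16))
        out.extend(block[block > lower].tolist())
    return out[:n]


def generate_organoid_experiment(
    config: OrganoidFixtureConfig,
) -> tuple[list[OrganoidExperiment], FixtureTruth]:
    """Generate paired control / treated (/ CSE) organoid readouts.

    Per replicate, each seeded cell gets one uniform propensity draw shared
    across conditions; a cell forms an organoid under a condition when its
    draw falls below that condition's CFE probability. Marginally each
    condition's count is Binomial(n_seeded, p_condition) while pairs are
    positively coupled — the generative meaning of a paired design in which
    conditions share the cell isolate. Diameters are lognormal truncated at
    50 µm; type counts are multinomial at fixed proportions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_ctrl = config.baseline_cfe
    probs = {"control": p_ctrl, "treated": p_ctrl * config.treatment_cfe_ratio}
    log_shift = {"control": 0.0, "treated": 0.0}
    if config.include_cse:
        probs["cse"] = p_ctrl * config.cse_cfe_ratio
        log_shift["cse"] = config.cse_diameter_log_shift

    experiments: list[OrganoidExperiment] = []
    for rep in range(1, config.n_replicates + 1):
        u = rng.random(config.n_seeded)
        for cond, p in probs.items():
            n_org = int((u < p).sum())
            diams = _truncated_lognormal(
                rng,
                n_org,
                config.diameter_log_mean + log_shift[cond],
                config.diameter_log_sd,
                50.0,
            )
            tc = rng.multinomial(n_org, _TYPE_PROPS)
            experiments.append(
                OrganoidExperiment(
                    condition=cond,
                    replicate_id=f"R{rep}",
                    n_seeded=config.n_seeded,
                    n_organoids=n_org,
                    diameters=diams,
                    type_counts=dict(zip(TYPE_CATEGORIES, tc.tolist())),
                )
            )
    truth = FixtureTruth(
        planted_effect_ratio=config.treatment_cfe_ratio,
        extras={
            "baseline_cfe": config.baseline_cfe,
            "cfe_probabilities": probs,
            "diameter_log_mean": config.diameter_log_mean,
            "diameter_log_sd": config.diameter_log_sd,
        },
    )
    return experiments, truth


# ---------------------------------------------------------------------------
# histology fixtures


@dataclass
class HistologyFixtureConfig:
    """Stained-field and airspace-mask generator settings.

    Intensities are on the 8-bit scale: ``positive_intensity_mean`` is the
    brightness the positive chromogen contributes to a stained pixel and
    ``background_intensity_mean`` the counterstain brightness of tissue.
    ``airspace_mode`` chooses a single air band of known width or
    non-overlapping air disks of known diameter (mean parallel-secant chord
    of a disk is pi * d / 4).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    positive_fraction: float = 0.3
    positive_intensity_mean: float = 100.0
    background_intensity_mean: float = 200.0
    airspace_mode: str = "band"  # band | disks
    band_width: float = 40.0  # µm
    disk_diameter: float = 80.0  # µm
    n_disks: int = 5
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 8 or w < 8:
            raise ValueError("image too small")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        for name in ("positive_intensity_mean", "background_intensity_mean"):
            v = getattr(self, name)
            if not 1 <= v <= 255:
                raise ValueError(f"{name} must be within [1, 255]")
        if self.airspace_mode not in ("band", "disks"):
            raise ValueError("airspace_mode must be 'band' or 'disks'")


def generate_ihc_image(
    config: HistologyFixtureConfig,
) -> tuple[StainImage, FixtureTruth]:
    """Forward stain-mixed RGB field with a planted positive fraction.

    All pixels carry counterstain; an exact ``positive_fraction`` of them
    additionally carry the chromogen. Per-pixel concentrations get 5%
    multiplicative noise; intensities follow Beer–Lambert mixing on the two
    default stain vectors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    n_px = h * w
    n_pos = int(round(config.positive_fraction * n_px))
    pos_flat = rng.choice(n_px, size=n_pos, replace=False)
    pos_mask = np.zeros(n_px, dtype=bool)
    pos_mask[pos_flat] = True

    c_hema = -math.log(config.background_intensity_mean / 255.0)
    c_red = -math.log(config.positive_intensity_mean / 255.0)
    conc_h = c_hema * (1.0 + 0.05 * rng.standard_normal(n_px))
    conc_r = np.where(
        pos_mask, c_red * (1.0 + 0.05 * rng.standard_normal(n_px)), 0.0
    )
    conc = np.clip(np.stack([conc_h, conc_r], axis=1), 0.0, None)
    od = conc @ DEFAULT_STAIN_VECTORS
    pixels = np.clip(np.rint(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)
    image = StainImage(
        pixels.reshape(h, w, 3), pixel_size=config.pixel_size, field_id="ihc"
    )
    truth = FixtureTruth(
        planted_positive_fraction=n_pos / n_px,
        extras={
            "n_positive_pixels": int(n_pos),
            "stain_vectors": DEFAULT_STAIN_VECTORS.tolist(),
            "positive_concentration": c_red,
            "background_concentration": c_hema,
        },
    )
    return image, truth


def generate_alveolar_mask(
    config: HistologyFixtureConfig,
) -> tuple[BinaryMask, FixtureTruth]:
    """Binary airspace mask with an analytically known mean chord.

    Band mode plants one vertical air band of the configured width
    (constant horizontal chords = band width). Disk mode plants
    non-overlapping air disks away from the border (mean parallel-secant
    chord = pi * d / 4); placement uses rejection sampling and fails loudly
    if the geometry cannot fit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    mask = np.zeros((h, w), dtype=bool)

    if config.airspace_mode == "band":
        width_px = int(round(config.band_width / config.pixel_size))
        if width_px < 1 or width_px > w - 4:
            raise ValueError("band does not fit within image bounds")
        start = (w - width_px) // 2
        mask[:, start : start + width_px] = True
        planted_chord = width_px * config.pixel_size
        geom_area_px = h * width_px
    else:
        radius_px = config.disk_diameter / (2.0 * config.pixel_size)
        margin = radius_px + 2.0
        if 2 * margin >= min(h, w):
            raise ValueError("disk diameter does not fit within image bounds")
        centers: list[tuple[float, float]] = []
        max_attempts = 10_000 * max(config.n_disks, 1)
        attempts = 0
        while len(centers) < config.n_disks:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "could not place non-overlapping disks; reduce n_disks "
                    "or disk_diameter"
                )
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 > (2 * radius_px + 2) ** 2
                for y, x in centers
            ):
                centers.append((cy, cx))
        yy, xx = np.mgrid[0:h, 0:w]
        for cy, cx in centers:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        planted_chord = math.pi * config.disk_diameter / 4.0
        geom_area_px = config.n_disks * math.pi * radius_px**2

    truth = FixtureTruth(
        planted_mean_chord=planted_chord,
        extras={
            "airspace_mode": config.airspace_mode,
            "planted_air_area_fraction": geom_area_px / (h * w),
        },
    )
    return BinaryMask(mask, semantics="airspace"), truth
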