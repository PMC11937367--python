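"""Secretome candidate-prioritization funnel.

A conditioned-medium proteome is measured in two compartments — an
extracellular-vesicle (EV) enriched fraction and the soluble-factor (SF)
fraction — across R biological replicates each. Candidate paracrine factors
are prioritized through a fixed sequence of binary filters:

1. identified in at least one replicate (per compartment),
2. consistently detected in all R replicates (per compartment),
3. compartment partition (EV-only / SF-only / both),
4. annotated as a growth factor or cytokine (gene-set membership),
5. predicted secreted by sequence-based predictors (e.g. SignalP, Phobius),
6. has a receptor partner expressed in the target recipient cells
   (alveolar epithelial AT1/AT2 cells by default).

Candidates are unordered: the funnel applies the paper-style binary filters
and reports provenance, it does not rank.

The module is organised statsmodels-style: :class:`SecretomeFunnel` is built
from a :class:`DetectionTable` and an :class:`AnnotationBundle`; its
:meth:`~SecretomeFunnel.run` returns a :class:`FunnelResult` with per-stage
counts, surviving sets and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._util import EV, FRACTIONS, SF, normalize_symbol, normalize_symbols

__all__ = [
    "DetectionTable",
    "AnnotationBundle",
    "VennPartition",
    "Candidate",
    "FunnelResult",
    "SecretomeFunnel",
    "consistent_proteins",
    "venn_partition",
    "annotate_factors",
    "secretion_filter",
    "receptor_filter",
    "run_funnel",
    "marker_enrichment",
    "expression_flags_from_matrix",
]

STAGES = (
    "identified",
    "consistent",
    "venn",
    "growth_factor",
    "secreted",
    "receptor_matched",
)


class DetectionTable:
    """Per-protein, per-fraction, per-replicate detection records.

    Wraps a tidy DataFrame with columns ``protein_id``, ``gene_symbol``,
    ``fraction`` (EV|SF), ``replicate`` (1..R) and ``detected`` (bool).
    ``(protein_id, fraction, replicate)`` must be unique and the replicate
    set must be identical for all proteins within a fraction.
    """

    REQUIRED = ("protein_id", "gene_symbol", "fraction", "replicate", "detected")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"detection table missing columns: {missing}")
        df["gene_symbol"] = df["gene_symbol"].map(normalize_symbol)
        df["fraction"] = df["fraction"].astype(str).str.upper()
        bad = set(df["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        df["detected"] = df["detected"].astype(bool)
        key = ["protein_id", "fraction", "replicate"]
        if df.duplicated(key).any():
            dup = df[df.duplicated(key, keep=False)].iloc[0]
            raise ValueError(
                "duplicate (protein_id, fraction, replicate) record: "
                f"{tuple(dup[key])}"
            )
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        dialect: Mapping[str, str] | None = None,
        intensity_threshold: float = 0.0,
    ) -> "DetectionTable":
        """Build from a DataFrame with possibly non-canonical column names.

        ``dialect`` maps canonical names to the frame's column names. An
        ``intensity`` column (canonical or mapped) is binarized as
        ``detected := intensity > intensity_threshold``.
        """
        df = frame.copy()
        if dialect:
            rename = {src: canon for canon, src in dialect.items() if src in df}
            df = df.rename(columns=rename)
        if "detected" not in df.columns:
            if "intensity" not in df.columns:
                raise ValueError("need a 'detected' or 'intensity' column")
            inten = pd.to_numeric(df["intensity"], errors="raise")
            if (inten < 0).any():
                raise ValueError("intensities must be >= 0")
            df["detected"] = inten > intensity_threshold
        return cls(df[[c for c in df.columns if c in cls.REQUIRED]])

    def replicates(self, fraction: str) -> list[int]:
        sub = self.frame[self.frame["fraction"] == fraction]
        return sorted(sub["replicate"].unique())

    def fractions(self) -> list[str]:
        return sorted(self.frame["fraction"].unique())

    def detected_counts(self, fraction: str) -> pd.Series:
        """Number of replicates each gene is detected in, for one fraction."""
        sub = self.frame[
            (self.frame["fraction"] == fraction) & self.frame["detected"]
        ]
        return sub.groupby("gene_symbol")["replicate"].nunique()

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DetectionTable):
            return NotImplemented
        key = ["protein_id", "fraction", "replicate"]
        a = self.frame.sort_values(key).reset_index(drop=True)
        b = other.frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)


@dataclass
class AnnotationBundle:
    """The funnel's annotation filters.

    Parameters
    ----------
    growth_factor_cytokine_set
        Gene symbols annotated as growth factors / cytokines (from GMT).
    secretion_calls
        gene symbol -> {predictor name: bool}; at least one named predictor.
    ligand_receptor_pairs
        Set of (ligand gene, receptor gene) tuples.
    receptor_expression
        (receptor gene, cell type) -> expressed flag.
    target_cell_types
        Recipient cell types; default alveolar AT1 and AT2 cells.
    """

    growth_factor_cytokine_set: set[str]
    secretion_calls: dict[str, dict[str, bool]]
    ligand_receptor_pairs: set[tuple[str, str]]
    receptor_expression: dict[tuple[str, str], bool]
    target_cell_types: set[str] = field(default_factory=lambda: {"AT1", "AT2"})

    def __post_init__(self):
        self.growth_factor_cytokine_set = normalize_symbols(
            self.growth_factor_cytokine_set
        )
        self.secretion_calls = {
            normalize_symbol(g): {str(p): bool(v) for p, v in calls.items()}
            for g, calls in self.secretion_calls.items()
        }
        self.ligand_receptor_pairs = {
            (normalize_symbol(l), normalize_symbol(r))
            for l, r in self.ligand_receptor_pairs
        }
        self.target_cell_types = {str(c).upper() for c in self.target_cell_types}
        expr = {}
        for (rec, cell), flag in self.receptor_expression.items():
            cell = str(cell).upper()
            if cell not in self.target_cell_types:
                raise ValueError(
                    f"expression flag for undeclared cell type {cell!r}"
                )
            expr[(normalize_symbol(rec), cell)] = bool(flag)
        self.receptor_expression = expr

    @property
    def predictors(self) -> list[str]:
        names: set[str] = set()
        for calls in self.secretion_calls.values():
            names.update(calls)
        return sorted(names)

    def receptors_of(self, ligand: str) -> set[str]:
        ligand = normalize_symbol(ligand)
        return {r for (l, r) in self.ligand_receptor_pairs if l == ligand}


@dataclass(frozen=True)
class VennPartition:
    """Disjoint EV-only / SF-only / shared partition of two gene sets."""

    ev_only: frozenset[str]
    sf_only: frozenset[str]
    both: frozenset[str]

    def provenance(self, gene: str) -> str:
        if gene in self.both:
            return "both"
        if gene in self.ev_only:
            return "EV_only"
        if gene in self.sf_only:
            return "SF_only"
        raise KeyError(gene)

    @property
    def union(self) -> frozenset[str]:
        return self.ev_only | self.sf_only | self.both


@dataclass(frozen=True)
class Candidate:
    gene_symbol: str
    provenance: str  # EV_only | SF_only | both
    receptors: tuple[str, ...]
    cell_types: tuple[str, ...]


@dataclass
class FunnelResult:
    """Per-stage counts, surviving sets and final candidates."""

    stage_counts: list[tuple[str, int, dict[str, int]]]
    surviving_sets: dict[str, set[str]]
    candidates: list[Candidate]
    dropped: dict[str, str] = field(default_factory=dict)
    venn: VennPartition | None = None
    options: dict = field(default_factory=dict)

    @property
    def candidate_set(self) -> set[str]:
        return {c.gene_symbol for c in self.candidates}

    def to_dict(self) -> dict:
        return {
            "stage_counts": [
                {"stage": s, "count": n, "per_compartment": per}
                for s, n, per in self.stage_counts
            ],
            "surviving_sets": {k: sorted(v) for k, v in self.surviving_sets.items()},
            "candidates": [
                {
                    "gene_symbol": c.gene_symbol,
                    "provenance": c.provenance,
                    "receptors": list(c.receptors),
                    "cell_types": list(c.cell_types),
                }
                for c in self.candidates
            ],
            "dropped": dict(self.dropped),
            "options": dict(self.options),
        }

    def summary(self) -> str:
        lines = ["Secretome prioritization funnel", "=" * 34]
        for stage, n, per in self.stage_counts:
            per_s = (
                " (" + ", ".join(f"{k}={v}" for k, v in per.items()) + ")"
                if per
                else ""
            )
            lines.append(f"{stage:<18} {n:>6}{per_s}")
        lines.append("")
        lines.append("Candidates (unordered):")
        for c in sorted(self.candidates, key=lambda c: c.gene_symbol):
            lines.append(
                f"  {c.gene_symbol:<12} {c.provenance:<8} "
                f"receptors={','.join(c.receptors) or '-'} "
                f"cells={','.join(c.cell_types) or '-'}"
            )
        return "\n".join(lines)


def consistent_proteins(
    table: DetectionTable, fraction: str, min_replicates: int | None = None
) -> set[str]:
    """Genes detected in at least ``min_replicates`` replicates of a fraction.

    Default requires detection in all R replicates of that fraction
    ("consistently present in all replicates"); ``min_replicates=1`` gives
    the identified-at-least-once universe.
    """
    fraction = str(fraction).upper()
    if fraction not in table.fractions():
        raise ValueError(f"fraction {fraction!r} absent from table")
    reps = table.replicates(fraction)
    r = len(reps)
    if min_replicates is None:
        min_replicates = r
    if not 1 <= min_replicates <= r:
        raise ValueError(f"min_replicates must be in 1..{r}")
    counts = table.detected_counts(fraction)
    return set(counts.index[counts >= min_replicates])


def venn_partition(ev_set: Iterable[str], sf_set: Iterable[str]) -> VennPartition:
    ev = normalize_symbols(ev_set) if ev_set else set()
    sf = normalize_symbols(sf_set) if sf_set else set()
    return VennPartition(
        ev_only=frozenset(ev - sf),
        sf_only=frozenset(sf - ev),
        both=frozenset(ev & sf),
    )


def annotate_factors(candidates: Iterable[str], bundle: AnnotationBundle) -> set[str]:
    """Intersect candidates with the growth-factor/cytokine gene set."""
    if not bundle.growth_factor_cytokine_set:
        raise ValueError("growth-factor/cytokine gene set is empty (not loaded?)")
    return normalize_symbols(candidates) & bundle.growth_factor_cytokine_set


def secretion_filter(
    factors: Iterable[str],
    bundle: AnnotationBundle,
    mode: str = "any",
    missing_policy: str = "not_secreted",
) -> set[str]:
    """Keep factors predicted secreted by the sequence predictors.

    ``mode='any'`` keeps a factor called secreted by at least one predictor
    (default); ``mode='all'`` requires every predictor to agree. Factors
    without any call are treated per ``missing_policy`` (default: dropped).
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    if missing_policy not in ("not_secreted", "secreted", "error"):
        raise ValueError("unknown missing_policy")
    if not bundle.predictors:
        raise ValueError("annotation bundle declares no secretion predictors")
    kept: set[str] = set()
    for gene in normalize_symbols(factors):
        calls = bundle.secretion_calls.get(gene)
        if not calls:
            if missing_policy == "error":
                raise ValueError(f"no secretion call for {gene}")
            if missing_policy == "secreted":
                kept.add(gene)
            continue
        votes = list(calls.values())
        if (mode == "any" and any(votes)) or (mode == "all" and all(votes)):
            kept.add(gene)
    return kept


def receptor_filter(
    factors: Iterable[str],
    bundle: AnnotationBundle,
    venn: VennPartition | None = None,
) -> tuple[list[Candidate], dict[str, str]]:
    """Keep factors with a receptor partner expressed in a target cell type.

    Returns (candidates, dropped) where ``dropped`` maps each removed gene
    to a human-readable reason (missing pair entries are logged, not errors).
    """
    candidates: list[Candidate] = []
    dropped: dict[str, str] = {}
    for gene in sorted(normalize_symbols(factors)):
        receptors = bundle.receptors_of(gene)
        if not receptors:
            dropped[gene] = "no known receptor"
            continue
        matched: list[str] = []
        cells: set[str] = set()
        for rec in sorted(receptors):
            rec_cells = {
                cell
                for cell in bundle.target_cell_types
                if bundle.receptor_expression.get((rec, cell), False)
            }
            if rec_cells:
                matched.append(rec)
                cells |= rec_cells
        if not matched:
            dropped[gene] = "receptor(s) not expressed in target cells"
            continue
        prov = venn.provenance(gene) if venn is not None else "unknown"
        candidates.append(
            Candidate(gene, prov, tuple(matched), tuple(sorted(cells)))
        )
    return candidates, dropped


class SecretomeFunnel:
    """The prioritization funnel as a model object.

    Parameters
    ----------
    detections
        :class:`DetectionTable` of per-replicate detections in EV and SF.
    annotations
        :class:`AnnotationBundle` with the gene-set, secretion and
        ligand–receptor filters.
    secretion_mode
        'any' (default) or 'all' predictor agreement for the secretion stage.
    min_replicates
        Replicate-consistency requirement; default all replicates.
    """

    def __init__(
        self,
        detections: DetectionTable,
        annotations: AnnotationBundle,
        secretion_mode: str = "any",
        min_replicates: int | None = None,
    ):
        self.detections = detections
        self.annotations = annotations
        self.secretion_mode = secretion_mode
        self.min_replicates = min_replicates

    def run(self) -> FunnelResult:
        table, bundle = self.detections, self.annotations
        present = table.fractions()

        def per_fraction(min_reps):
            return {
                f: consistent_proteins(table, f, min_reps) if f in present else set()
                for f in FRACTIONS
            }

        identified = per_fraction(1 if present else None) if present else {
            EV: set(), SF: set()
        }
        consistent = (
            per_fraction(self.min_replicates) if present else {EV: set(), SF: set()}
        )
        venn = venn_partition(consistent[EV], consistent[SF])
        gf = annotate_factors(venn.union, self.annotations) if venn.union else set()
        secreted = (
            secretion_filter(gf, bundle, mode=self.secretion_mode) if gf else set()
        )
        candidates, dropped = receptor_filter(secreted, bundle, venn)

        def venn_counts(genes: set[str]) -> dict[str, int]:
            return {
                "EV_only": len(genes & venn.ev_only),
                "SF_only": len(genes & venn.sf_only),
                "both": len(genes & venn.both),
            }

        cand_set = {c.gene_symbol for c in candidates}
        stage_counts = [
            (
                "identified",
                len(identified[EV] | identified[SF]),
                {EV: len(identified[EV]), SF: len(identified[SF])},
            ),
            (
                "consistent",
                len(consistent[EV] | consistent[SF]),
                {EV: len(consistent[EV]), SF: len(consistent[SF])},
            ),
            (
                "venn",
                len(venn.union),
                {
                    "EV_only": len(venn.ev_only),
                    "SF_only": len(venn.sf_only),
                    "both": len(venn.both),
                },
            ),
            ("growth_factor", len(gf), venn_counts(gf)),
            ("secreted", len(secreted), venn_counts(secreted)),
            ("receptor_matched", len(cand_set), venn_counts(cand_set)),
        ]
        surviving = {
            "identified": identified[EV] | identified[SF],
            "consistent": consistent[EV] | consistent[SF],
            "venn": set(venn.union),
            "growth_factor": set(gf),
            "secreted": set(secreted),
            "receptor_matched": cand_set,
        }
        return FunnelResult(
            stage_counts=stage_counts,
            surviving_sets=surviving,
            candidates=candidates,
            dropped=dropped,
            venn=venn,
            options={
                "secretion_mode": self.secretion_mode,
                "min_replicates": self.min_replicates,
            },
        )


def run_funnel(
    table: DetectionTable,
    bundle: AnnotationBundle,
    secretion_mode: str = "any",
    min_replicates: int | None = None,
) -> FunnelResult:
    """Functional entry point; see :class:`SecretomeFunnel`."""
    return SecretomeFunnel(table, bundle, secretion_mode, min_replicates).run()


def marker_enrichment(
    table: DetectionTable, marker_set: Iterable[str]
) -> tuple[float, float, np.ndarray]:
    """Enrichment of marker proteins in EV- vs SF-consistent sets.

    Builds the 2x2 table (marker / non-marker x EV-consistent /
    SF-consistent) and returns (odds ratio, two-sided hypergeometric exact
    p, counts). Used for MISEV-style checks that vesicle-associated
    (transmembrane / GPI-anchored) proteins are enriched in the EV fraction.
    A zero-margin table gets a Haldane continuity correction for the odds
    ratio (p-value from the uncorrected table); an all-EV marker pattern
    yields an infinite odds-ratio sentinel.
    """
    markers = normalize_symbols(marker_set)
    if not markers:
        raise ValueError("marker set is empty")
    ev = consistent_proteins(table, EV)
    sf = consistent_proteins(table, SF)
    counts = np.array(
        [
            [len(ev & markers), len(sf & markers)],
            [len(ev - markers), len(sf - markers)],
        ]
    )
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        # degenerate margin: report continuity-corrected odds ratio
        c = counts + 0.5
        odds = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    elif counts[0, 1] == 0 or counts[1, 0] == 0:
        odds = float("inf")
    return float(odds), float(p), counts


def expression_flags_from_matrix(
    expression: pd.DataFrame, fraction_threshold: float = 0.10
) -> dict[tuple[str, str], bool]:
    """Build boolean receptor-expression flags from a fraction-of-cells matrix.

    ``expression`` is receptors x cell types with values = fraction of cells
    of that type expressing the receptor; a receptor counts as expressed in
    a cell type when the fraction is >= ``fraction_threshold`` (default 10%).
    """
    if not 0 <= fraction_threshold <= 1:
        raise ValueError("fraction_threshold must be in [0,1]")
    flags: dict[tuple[str, str], bool] = {}
    for rec in expression.index:
        for cell in expression.columns:
            flags[(normalize_symbol(rec), str(cell).upper())] = bool(
                float(expression.loc[rec, cell]) >= fraction_threshold
            )
    return flags
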