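import pandas as pd
import pytest

from secrepair.funnel import AnnotationBundle, DetectionTable


def make_detection_frame(records):
    """records: (protein, gene, fraction, replicate, detected) tuples."""
    return pd.DataFrame(
        records,
        columns=["protein_id", "gene_symbol", "fraction", "replicate", "detected"],
    )


@pytest.fixture
def toy_table():
    """10 proteins x 4 EV replicates; proteins 1-6 consistent, 7-10 partial."""
    rows = []
    for i in range(1, 11):
        for rep in range(1, 5):
            detected = i <= 6 or rep <= (i - 7)  # 7 -> 0 reps, 10 -> 3 reps
            rows.append((f"P{i}", f"G{i}", "EV", rep, detected))
        for rep in range(1, 5):
            rows.append((f"P{i}", f"G{i}", "SF", rep, i % 2 == 0))
    return DetectionTable(make_detection_frame(rows))


@pytest.fixture
def small_bundle():
    return AnnotationBundle(
        growth_factor_cytokine_set={"GF1", "GF2", "GF3"},
        secretion_calls={
            "GF1": {"SignalP": True, "Phobius": False},
            "GF2": {"SignalP": False, "Phobius": False},
            "GF3": {"SignalP": True, "Phobius": True},
        },
        ligand_receptor_pairs={("GF1", "R1"), ("GF3", "R3")},
        receptor_expression={
            ("R1", "AT2"): True,
            ("R1", "AT1"): False,
            ("R3", "AT1"): False,
            ("R3", "AT2"): False,
        },
    )
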