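"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

from monopred import synthdata

# gene panel used by the case-deletion fixtures: moderate size so a real
# top-k ranking exists, lognormal baseline means
_PANEL_RNG = np.random.default_rng(20240917)
CDD_PANEL = {f"G{i:03d}": float(m) for i, m in
             enumerate(_PANEL_RNG.lognormal(0.7, 0.6, 300))}


def make_cdd_cohort(seed: int, aberrant: bool):
    """A 5v4-sample cohort with per-gene monocyte fold changes.

    When ``aberrant``, sample P03 (responder group) gets an independent
    large-amplitude fold-change pattern replacing the shared group effect,
    making its deletion profile an outlier.
    """
    r = np.random.default_rng(seed)
    fc = {g: float(r.normal(0.0, 1.0)) for g in CDD_PANEL}
    ab = {"P03": {g: float(r.normal(0.0, 3.0)) for g in CDD_PANEL}} if aberrant else {}
    spec = synthdata.CellSimSpec(
        n_samples={synthdata.RESPONDER: 5, synthdata.NONRESPONDER: 4},
        cells_per_sample=200, panel=CDD_PANEL, group_log2fc=fc,
        aberrant_samples=ab, seed=seed,
    )
    return synthdata.gen_cells(spec)


@pytest.fixture(scope="session")
def noiseless_image():
    spec = synthdata.ImageSimSpec(noise_sd=0.0, background_amplitude=0.0, seed=42)
    return synthdata.gen_image(spec)


@pytest.fixture(scope="session")
def small_cells():
    return synthdata.gen_cells(synthdata.CellSimSpec(cells_per_sample=150, seed=5))


def expected_rule_counts(truth):
    """Ground-truth A1..A4 counts implied by the phenotype marker map."""
    mm = synthdata.PHENOTYPE_MARKERS
    counts = truth["phenotype"].value_counts().to_dict()

    def total(pred):
        return sum(v for k, v in counts.items() if pred(mm[k]))

    return {
        "A1": total(lambda m: m["CD16"] and not m["CD14"]),
        "A2": total(lambda m: m["CD14"] or m["CD16"]),
        "A3": total(lambda m: m["APOBEC3A"] and (m["CD14"] or m["CD16"])),
        "A4": total(lambda m: m["APOBEC3A"]),
        "classical": total(lambda m: m["CD14"] and not m["CD16"]),
    }
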