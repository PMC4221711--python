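"""Shared fixtures: independent oracles and synthetic benchmark tables."""

import numpy as np
import pandas as pd
import pytest

from tracefate.simulate import ScreenDesign, simulate_metabolomics


def binomial_convolve(mid: np.ndarray, p13: float) -> np.ndarray:
    """Independent forward model of natural-abundance smearing.

    A molecule with j tracer carbons and N-j natural carbons is observed at
    shift j + (number of natural 13C), built here by explicit polynomial
    convolution of per-carbon [1-p, p] factors -- no binomial pmf calls, no
    matrix, independent of the implementation under test.
    """
    n = len(mid) - 1
    out = np.zeros(n + 1)
    for j, frac in enumerate(mid):
        dist = np.array([1.0])
        for _ in range(n - j):
            dist = np.convolve(dist, [1.0 - p13, p13])
        out[j : j + len(dist)] += frac * dist
    return out


def random_mid(rng: np.random.Generator, n_carbons: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n_carbons + 1))
    return x


@pytest.fixture(scope="session")
def synthetic_table_s1() -> pd.DataFrame:
    """SYNTHETIC stand-in for a published cross-cell-line metabolomics
    supplement that is not redistributable here.

    400 metabolites x 3 cell-line models x (parental, mesenchymal) x 5
    replicates, with exactly 10 metabolites planted to change consistently
    in all three models (FC 4 or 1/4, sigma 0.1), of which 5 carry
    amino-acid or peptide annotations (the category composition the real
    supplement reports).  The generator world is the ground truth; no real
    measurement is contained or claimed.
    """
    planted = {
        # amino-acid / peptide hits (5)
        "glutamine": 4.0,
        "tryptophan": 4.0,
        "glutathione, reduced": 4.0,
        "4-guanidinobutanoate": 4.0,
        "cysteinylglycine": 4.0,
        # other-category hits (5)
        "hit_lipid_1": 0.25,
        "hit_lipid_2": 4.0,
        "hit_carb_1": 0.25,
        "hit_nuc_1": 4.0,
        "hit_nuc_2": 0.25,
    }
    pathway_of = {
        "glutathione, reduced": "peptide",
        "cysteinylglycine": "peptide",
        "4-guanidinobutanoate": "amino acid",
        "hit_lipid_1": "lipid",
        "hit_lipid_2": "lipid",
        "hit_carb_1": "carbohydrate",
        "hit_nuc_1": "nucleotide",
        "hit_nuc_2": "nucleotide",
    }
    names = (
        list(planted)
        + [a for a in
           ("alanine", "arginine", "asparagine", "aspartate", "cysteine",
            "glutamate", "glycine", "histidine", "isoleucine", "leucine",
            "lysine", "methionine", "phenylalanine", "proline", "serine",
            "threonine", "tyrosine", "valine")]
        + [f"null{i:04d}" for i in range(400 - 10 - 18)]
    )
    design = ScreenDesign(
        n_models=3, n_replicates=5, n_features=len(names),
        planted_effects=planted, sigma=0.1,
    )
    return simulate_metabolomics(
        design, seed=20150918, feature_names=names, pathway_of=pathway_of
    )
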