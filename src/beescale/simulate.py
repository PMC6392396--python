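"""Synthetic specimen tables and trees with known generating truth.

The generator emulates the structure of a multi-continent pollinator
trait survey: species grouped into families, each species endemic to
one biogeographic region, per-species lognormal ITD, and dry weight
following a family- and sex-specific power law with region- and
species-level random intercepts plus ln-scale residual noise.  Trees
come from a birth-death genus backbone with species grafted as
equal-branch-length polytomies, and traits evolve on them by Brownian
motion -- exactly the assumptions of the fitting code, so every
downstream stage can be tested against known truth.

Default effect sizes (slope 2.6, male offset -0.3, region/species/
residual SDs 0.2/0.4/0.3, 40 species x 10 specimens) are chosen inside
the range of allometric exponents and variability observed in real bee
data; they are synthetic study conditions, not estimates.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass

import dendropy
import numpy as np
import pandas as pd

from .records import REGIONS
from .trees import Phylogeny, graft_species_polytomies, phylo_covariance

__all__ = ["GeneratorTruth", "generate_specimens", "generate_backbone",
           "generate_tree", "simulate_bm_trait"]

_FAMILIES = ("Apidae", "Halictidae", "Andrenidae", "Megachilidae",
             "Colletidae", "Melittidae")


@dataclass(frozen=True)
class GeneratorTruth:
    """Everything the specimen generator needs, and nothing hidden.

    Per-(group, sex) coefficients are composed as
    ``lnalpha_by_group[g] + sex_offset*(male)`` and
    ``beta_by_group[g] + sex_slope_offset*(male)``.
    """

    n_regions: int = 3
    n_groups: int = 4
    species_per_group: int = 10
    specimens_per_species_sex: int = 5
    lnalpha_by_group: tuple[float, ...] = (1.0, 0.7, 1.3, 0.5)
    beta_by_group: tuple[float, ...] = (2.6, 2.6, 2.6, 2.6)
    sex_offset: float = -0.3
    sex_slope_offset: float = 0.0
    region_sd: float = 0.2
    species_sd: float = 0.4
    resid_sd: float = 0.3
    itd_median_mm: float = 2.0
    itd_ln_sd: float = 0.45
    itd_specimen_ln_sd: float = 0.08
    include_body_length: bool = True
    bl_lnalpha: float = 0.9
    bl_exponent: float = 1.0
    bl_ln_sd: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.n_regions <= len(REGIONS)):
            raise ValueError(f"n_regions must be in 1..{len(REGIONS)}")
        if not (1 <= self.n_groups <= len(_FAMILIES)):
            raise ValueError(f"n_groups must be in 1..{len(_FAMILIES)}")
        if min(self.species_per_group, self.specimens_per_species_sex) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("region_sd", "species_sd", "resid_sd", "itd_ln_sd",
                     "itd_specimen_ln_sd", "bl_ln_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.lnalpha_by_group) < self.n_groups or len(self.beta_by_group) < self.n_groups:
            raise ValueError("need lnalpha/beta for every group")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named substreams so adding a field never perturbs existing draws."""
    root = np.random.SeedSequence(seed)
    names = ("assign", "itd", "effects", "noise", "bl")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_specimens(truth: GeneratorTruth) -> tuple[pd.DataFrame, dict]:
    """Draw a specimen table from the truth; deterministic given the seed.

    Returns the table plus a truth echo: the input parameters and every
    realized latent quantity (region and species intercepts, species
    home regions, median ITDs).  The table also carries a
    ``true_ln_mean`` column (the noise-free ln dry weight of each
    record) for calibration checks; readers that don't know it simply
    ignore it.
    """
    rng = _streams(truth.seed)
    regions = list(REGIONS[: truth.n_regions])
    region_eff = dict(zip(regions, rng["effects"].normal(0, truth.region_sd, len(regions))))

    species_meta = {}
    rows = []
    sid = 0
    for g in range(truth.n_groups):
        family = _FAMILIES[g]
        for j in range(truth.species_per_group):
            genus = f"Genus{g:02d}{j // 2:02d}"
            species = f"{genus} sp{j:02d}"
            home = regions[int(rng["assign"].integers(len(regions)))]
            sp_eff = float(rng["effects"].normal(0, truth.species_sd))
            median_itd = truth.itd_median_mm * float(
                np.exp(rng["itd"].normal(0, truth.itd_ln_sd))
            )
            species_meta[species] = {
                "group": family, "genus": genus, "region": home,
                "species_effect": sp_eff, "median_itd_mm": median_itd,
            }
            for sex_idx, sex in enumerate(("female", "male")):
                lnalpha = truth.lnalpha_by_group[g] + truth.sex_offset * sex_idx
                beta = truth.beta_by_group[g] + truth.sex_slope_offset * sex_idx
                for _ in range(truth.specimens_per_species_sex):
                    itd = median_itd * float(
                        np.exp(rng["itd"].normal(0, truth.itd_specimen_ln_sd))
                    )
                    mu = (lnalpha + beta * np.log(itd)
                          + region_eff[home] + sp_eff)
                    lnw = mu + float(rng["noise"].normal(0, truth.resid_sd))
                    row = {
                        "specimen_id": f"sim{sid:05d}",
                        "species": species,
                        "genus": genus,
                        "group": family,
                        "sex": sex,
                        "region": home,
                        "itd_mm": itd,
                        "dry_weight_mg": float(np.exp(lnw)),
                        "true_ln_mean": float(mu),
                    }
                    if truth.include_body_length:
                        row["body_length_mm"] = float(np.exp(
                            truth.bl_lnalpha + truth.bl_exponent * np.log(itd)
                            + rng["bl"].normal(0, truth.bl_ln_sd)
                        ))
                    rows.append(row)
                    sid += 1

    table = pd.DataFrame(rows)
    echo = {
        "truth": asdict(truth),
        "region_effects": region_eff,
        "species": species_meta,
    }
    return table, echo


def generate_backbone(n_genera: int, seed: int = 1) -> Phylogeny:
    """Pure-birth ultrametric genus backbone rescaled to unit depth."""
    if n_genera < 2:
        raise ValueError("need >= 2 genera")
    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace([f"Genus{i:02d}" for i in range(n_genera)])
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=n_genera,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    depth = max(Phylogeny(tree).tip_depths().values())
    if depth == 0:  # the 2-tip simulation can stop at the initial split
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
        depth = 1.0
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    return Phylogeny(tree)


def generate_tree(
    n_genera: int,
    species_per_genus: int,
    seed: int = 1,
    fraction: float = 0.5,
) -> tuple[Phylogeny, dict[str, str]]:
    """Random ultrametric genus backbone with grafted species polytomies.

    The backbone is a pure-birth tree rescaled to unit depth; each genus
    tip then receives ``species_per_genus`` species as an equal-length
    polytomy.  Returns the species-level tree and the species -> genus
    mapping used for the graft.
    """
    if species_per_genus < 1:
        raise ValueError("need >= 1 species per genus")
    backbone = generate_backbone(n_genera, seed=seed)

    mapping = {
        f"Genus{i:02d} sp{j:02d}": f"Genus{i:02d}"
        for i in range(n_genera)
        for j in range(species_per_genus)
    }
    grafted, excluded = graft_species_polytomies(backbone, mapping, fraction=fraction)
    assert not excluded
    return grafted, mapping


def simulate_bm_trait(
    tree: Phylogeny,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    seed: int = 1,
    mean: float = 0.0,
) -> dict[str, float]:
    """Simulate a species trait with lambda-scaled Brownian covariance.

    ``lambda_true`` interpolates between independent tip values (0) and
    full Brownian-motion covariance on the tree (1), exactly the family
    of models the signal estimator fits.
    """
    if not (0 <= lambda_true <= 1):
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    C = phylo_covariance(tree).to_numpy()
    labels = tree.tip_labels
    V = sigma2 * (lambda_true * C + (1 - lambda_true) * np.diag(np.diag(C)))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    z = np.random.default_rng(seed).standard_normal(len(labels))
    y = mean + L @ z
    return dict(zip(labels, map(float, y)))
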