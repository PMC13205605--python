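"""Seeded generators emulating the data the method consumes.

Three generators cover the pipeline's inputs without any downloads:

* ``simulate_sc`` -- two-condition droplet scRNA-seq UMI counts with a
  negative-binomial noise model, log-normal library sizes, and planted
  fold changes on the 20 packaged ferroptosis-regulator genes (the
  dysregulation pattern the resistance signature is derived from).
* ``simulate_bulk`` -- small bulk cohorts (Gaussian log-expression,
  a few replicates per condition) with planted shifts on the signature
  genes.
* ``simulate_perturbations`` -- a LINCS-style perturbation library of
  per-gene z-like statistics containing null instances plus planted
  signature reversers and aggravators.

Every generator is a pure function of its parameters including the
seed, and returns a ground-truth table sufficient to score recovery
without re-deriving the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, Layer, PerturbationLibrary, RegulatorCatalog, Role
from .signature import ResistanceSignature, default_signature

#: Default seed for all randomness (mnemonic: the signature size).
DEFAULT_SEED = 20


def _decoy_names(n: int) -> list[str]:
    return [f"DECOY{i + 1:04d}" for i in range(n)]


def regulator_catalog(n_decoys: int = 50) -> RegulatorCatalog:
    """The packaged 20 signature regulators plus ``n_decoys`` decoy entries.

    Decoys alternate driver/suppressor roles; they carry no planted
    effect in the simulations, so a correct pipeline should never pull
    them into the signature.  The catalog emulates the role structure of
    a ferroptosis-regulator database, not its full gene list.
    """
    sig = default_signature()
    entries: dict[str, Role] = {g: Role.SUPPRESSOR for g in sig.up_suppressors}
    entries.update({g: Role.DRIVER for g in sig.down_drivers})
    for i, name in enumerate(_decoy_names(n_decoys)):
        entries[name] = Role.DRIVER if i % 2 == 0 else Role.SUPPRESSOR
    return RegulatorCatalog(entries=entries, source_label=f"synthetic catalog (+{n_decoys} decoys)")


@dataclass
class ScSimParams:
    """Parameters of the two-condition scRNA-seq count simulation.

    Counts are NegativeBinomial with mean
    ``libsize_c * baseline_g * 2**(lfc_g * [condition == resistant])``
    and a gamma-Poisson dispersion ``nb_dispersion`` (variance
    ``mu + dispersion * mu**2``); baselines and per-cell library-size
    factors are log-normal.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 500
    baseline_log_mean_mu: float = 0.5
    baseline_log_mean_sigma: float = 1.0
    nb_dispersion: float = 0.3
    libsize_log_sigma: float = 0.3
    planted_suppressor_lfc: float = 1.0
    planted_driver_lfc: float = -1.0
    n_background_de: int = 100
    background_lfc_magnitude: float = 1.0
    n_decoy_regulators: int = 50
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0 or self.libsize_log_sigma <= 0:
            raise ValueError("dispersion and libsize sigma must be positive")
        if self.n_cells_per_condition < 1:
            raise ValueError("need at least one cell per condition")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and var ``mean + disp*mean**2``."""
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_sc(params: ScSimParams) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a sensitive/resistant UMI count matrix with planted effects.

    The 8 packaged suppressor genes get ``planted_suppressor_lfc`` and
    the 12 driver genes ``planted_driver_lfc`` in the resistant
    condition; decoy catalog genes have zero fold change; a further
    ``n_background_de`` non-catalog genes get +/- the background
    magnitude.  Baselines for the planted regulator genes are drawn from
    the upper half of the baseline distribution (regulators in the
    emulated system are reliably detected genes); all other baselines
    are unconstrained log-normal draws.

    Returns the count matrix (condition-labelled, raw_counts layer) and
    a ground-truth table with one row per gene: its true lfc, its
    catalog role if any, and its simulation group.
    """
    sig = default_signature()
    n_planted = sig.n
    n_special = n_planted + params.n_decoy_regulators + params.n_background_de
    if params.n_genes < n_special:
        raise ValueError(
            f"n_genes={params.n_genes} cannot hold {n_planted} signature genes, "
            f"{params.n_decoy_regulators} decoys and {params.n_background_de} "
            "background DE genes"
        )
    rng = np.random.default_rng(params.seed)
    decoys = _decoy_names(params.n_decoy_regulators)
    background = [f"BG{i + 1:04d}" for i in range(params.n_background_de)]
    fillers = [f"GENE{i + 1:05d}" for i in range(params.n_genes - n_special)]
    gene_ids = sig.up_suppressors + sig.down_drivers + decoys + background + fillers

    lfc = np.zeros(params.n_genes)
    lfc[: len(sig.up_suppressors)] = params.planted_suppressor_lfc
    lfc[len(sig.up_suppressors) : n_planted] = params.planted_driver_lfc
    bg_slice = slice(n_planted + params.n_decoy_regulators, n_special)
    bg_signs = rng.choice([-1.0, 1.0], size=params.n_background_de)
    lfc[bg_slice] = bg_signs * params.background_lfc_magnitude

    mu, sigma = params.baseline_log_mean_mu, params.baseline_log_mean_sigma
    baseline = rng.lognormal(mu, sigma, size=params.n_genes)
    # planted regulators: redraw below-median baselines (expressed genes)
    floor = np.exp(mu)
    for i in range(n_planted):
        while baseline[i] < floor:
            baseline[i] = rng.lognormal(mu, sigma)

    n_cells = 2 * params.n_cells_per_condition
    condition = np.array(
        ["sensitive"] * params.n_cells_per_condition
        + ["resistant"] * params.n_cells_per_condition,
        dtype=object,
    )
    libsize = rng.lognormal(0.0, params.libsize_log_sigma, size=n_cells)
    resistant = (condition == "resistant").astype(float)
    mean = libsize[None, :] * baseline[:, None] * 2.0 ** (lfc[:, None] * resistant[None, :])
    counts = _nb_counts(rng, mean, params.nb_dispersion)

    catalog = regulator_catalog(params.n_decoy_regulators)
    group = (
        ["signature_suppressor"] * len(sig.up_suppressors)
        + ["signature_driver"] * len(sig.down_drivers)
        + ["decoy"] * params.n_decoy_regulators
        + ["background"] * params.n_background_de
        + ["noise"] * len(fillers)
    )
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "lfc": lfc,
            "catalog_role": [
                catalog.entries[g].value if g in catalog else "" for g in gene_ids
            ],
            "group": group,
        }
    )
    matrix = ExpressionMatrix(
        values=counts,
        gene_ids=gene_ids,
        obs_ids=[f"CELL{i + 1:05d}" for i in range(n_cells)],
        condition=condition,
        layer=Layer.RAW_COUNTS,
    )
    return matrix, truth


def simulate_bulk(
    n_replicates: int = 3,
    shift: float = 1.0,
    noise_sd: float = 0.5,
    n_background_genes: int = 200,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
    seed: int = DEFAULT_SEED,
) -> ExpressionMatrix:
    """Simulate a small bulk cohort with planted signature shifts.

    Log-expression of each gene is Gaussian around a gene-specific
    baseline; in the resistant condition the packaged suppressors move
    up by ``shift`` and the drivers down by ``shift``.  The replicate
    scale matches typical induced-resistance cell-line designs
    (``n_replicates`` per condition, default 3).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    sig = default_signature()
    rng = np.random.default_rng(seed)
    gene_ids = (
        sig.up_suppressors
        + sig.down_drivers
        + [f"BULKBG{i + 1:04d}" for i in range(n_background_genes)]
    )
    n_genes = len(gene_ids)
    delta = np.zeros(n_genes)
    delta[: len(sig.up_suppressors)] = shift
    delta[len(sig.up_suppressors) : sig.n] = -shift
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    n_samples = 2 * n_replicates
    condition = np.array(
        ["sensitive"] * n_replicates + ["resistant"] * n_replicates, dtype=object
    )
    resistant = (condition == "resistant").astype(float)
    values = (
        baseline[:, None]
        + delta[:, None] * resistant[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        obs_ids=[f"SAMPLE{i + 1:02d}" for i in range(n_samples)],
        condition=condition,
        layer=Layer.LOG_NORMALIZED,
    )


@dataclass
class PerturbSimParams:
    """Parameters of the perturbation-library simulation.

    Null instances carry iid Normal(0, noise_sd) statistics; reversers
    additionally shift the up-suppressor genes by ``-reverser_strength``
    and the down-driver genes by ``+reverser_strength`` (the signature-
    reversal pattern); aggravators apply the opposite shifts.
    """

    n_genes: int = 1000
    n_null_instances: int = 200
    n_reversers: int = 5
    n_aggravators: int = 5
    reverser_strength: float = 3.0
    noise_sd: float = 1.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.reverser_strength <= 0 or self.noise_sd <= 0:
            raise ValueError("reverser_strength and noise_sd must be positive")
        if self.n_genes < 20:
            raise ValueError("n_genes must cover the 20 signature genes")


def simulate_perturbations(
    params: PerturbSimParams,
) -> tuple[PerturbationLibrary, pd.DataFrame]:
    """Simulate a perturbation library with planted reversers/aggravators.

    Instance classes are assigned to randomly shuffled positions; the
    library metadata exposes only neutral instance and compound names,
    while the returned ground-truth table maps each instance to its
    true class (null / reverser / aggravator).
    """
    sig = default_signature()
    rng = np.random.default_rng(params.seed)
    n_inst = params.n_null_instances + params.n_reversers + params.n_aggravators
    gene_ids = sig.up_suppressors + sig.down_drivers + [
        f"PGENE{i + 1:05d}" for i in range(params.n_genes - sig.n)
    ]
    stats = rng.normal(0.0, params.noise_sd, size=(params.n_genes, n_inst))

    classes = np.array(
        ["reverser"] * params.n_reversers
        + ["aggravator"] * params.n_aggravators
        + ["null"] * params.n_null_instances,
        dtype=object,
    )
    classes = classes[rng.permutation(n_inst)]
    s = params.reverser_strength
    n_up = len(sig.up_suppressors)
    for j, cls in enumerate(classes):
        if cls == "reverser":
            stats[:n_up, j] -= s
            stats[n_up : sig.n, j] += s
        elif cls == "aggravator":
            stats[:n_up, j] += s
            stats[n_up : sig.n, j] -= s

    instance_ids = [f"INST{i + 1:04d}" for i in range(n_inst)]
    compound_names = [f"compound_{i + 1:04d}" for i in range(n_inst)]
    metadata = pd.DataFrame(
        {
            "instance_id": instance_ids,
            "compound_name": compound_names,
            "mode_of_action": ["unknown"] * n_inst,
        }
    )
    truth = pd.DataFrame(
        {
            "instance_id": instance_ids,
            "compound_name": compound_names,
            "class": classes,
        }
    )
    library = PerturbationLibrary(
        stat_matrix=stats,
        gene_ids=gene_ids,
        instance_ids=instance_ids,
        metadata=metadata,
    )
    return library, truth
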