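"""Synthetic quant experiments with a planted ground truth.

The generator emulates the structure of a two-genotype (autophagy-proficient
WT vs autophagy-null KO) x two-treatment (untreated vs nutrient-starved) TMT
experiment:

* *autophagy clients* lose abundance in starved WT cells and the loss is
  rescued (abolished) in the KO, the signature the consensus-RMSE classifier
  is built to detect;
* *known fluxers* are a labelled subset of clients that seed the consensus;
* *translation-suppressed* proteins lose abundance in both genotypes — the
  genotype-independent confounder the classifier must reject;
* *stable* proteins and *histones* (the proteome-ruler anchor) are flat.

Replicate noise is log-normal on the log2 scale.  Baseline copy numbers are
drawn log-uniform over five orders of magnitude.  Histone copies are rescaled
so that total histone protein mass equals the configured DNA mass per cell —
the physical anchor the proteome ruler assumes — which makes ruler recovery
exact in the noiseless limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .io import QuantExperiment, validate_annotations

logger = logging.getLogger("capcensus")

CLASS_LABELS = (
    "autophagy_client",
    "translation_suppressed",
    "stable",
    "known_fluxer",
    "histone",
)

# Clients + labelled fluxers total 10% of the proteome, matching the decile
# the CAP cut calls: the call is a fixed-size set, so the planted prevalence
# is the condition under which precision and recall are commensurable.
_DEFAULT_FRACTIONS = {
    "autophagy_client": 0.094,
    "translation_suppressed": 0.10,
    "stable": 0.796,
    "known_fluxer": 0.006,
    "histone": 0.004,
}

# Compartment mixtures per class: clients concentrate in the secretory
# membrane compartments, the translational confounder in cytosol/nucleus
# (ribosome-like), known fluxers mirror the validated receptor panel.
_DEFAULT_COMPARTMENTS = {
    "autophagy_client": {
        "Golgi": 0.30, "ER": 0.35, "cytosol": 0.10, "endosome": 0.10,
        "lysosome": 0.05, "mitochondria": 0.05, "plasma membrane": 0.05,
    },
    "translation_suppressed": {"cytosol": 0.80, "nucleus": 0.20},
    "stable": {
        "cytosol": 0.44, "nucleus": 0.25, "mitochondria": 0.10,
        "plasma membrane": 0.10, "ER": 0.04, "Golgi": 0.02,
        "endosome": 0.03, "lysosome": 0.02,
    },
    "known_fluxer": {"ER": 0.50, "cytosol": 0.50},
    "histone": {"nucleus": 1.0},
}

# Probability that a simulated Golgi protein is membrane-embedded (has TM
# segments) rather than peripherally associated.
_GOLGI_MEMBRANE_PROB = {"autophagy_client": 0.85, "known_fluxer": 0.85}
_GOLGI_MEMBRANE_PROB_DEFAULT = 0.5


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic census experiment.

    Defaults are the conditions the recovery properties are stated under:
    a one-log2 client depletion fully rescued by KO, 0.25 log2 replicate
    noise, three replicates per condition, 5,000 proteins.
    """

    n_proteins: int = 5000
    class_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    compartment_mixture: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COMPARTMENTS.items()}
    )
    client_effect: float = -1.0        # mean log2 depletion, WT starved
    rescue_fraction: float = 1.0       # share of client effect abolished in KO
    suppression_effect: float = -0.75  # genotype-independent log2 depletion
    receptor_effect_scale: float = 2.0  # receptors flux harder than mean client
    n_receptors: int = 2
    noise_sd: float = 0.25             # replicate log2 noise
    n_replicates: int = 3
    genotypes: tuple = ("WT", "KO")
    treatments: tuple = ("UT", "starved")
    copies_log10_range: tuple = (2.0, 7.0)  # five orders of magnitude
    dna_mass_pg: float = 6.5
    histone_dna_mass_ratio: float = 1.0
    experiment_id: str = "sim"
    seed: int | None = None

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ValueError("rescue_fraction must lie in [0, 1]")
        unknown = set(self.class_fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted per-protein truth: class label, true copies, receptor IDs."""

    labels: pd.Series        # protein_id -> class label
    true_copies: pd.Series   # protein_id -> copies per cell (untreated)
    receptors: list          # planted receptor protein IDs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"class": self.labels, "true_copies": self.true_copies})
        df["is_receptor"] = df.index.isin(self.receptors)
        df.index.name = "protein_id"
        return df


def _make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for g in config.genotypes:
        for t in config.treatments:
            for r in range(1, config.n_replicates + 1):
                rows.append(
                    dict(channel_id=f"{g}_{t}_r{r}", genotype=g, treatment=t,
                         replicate=r, experiment_id=config.experiment_id)
                )
    return pd.DataFrame(rows)


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_proteins
    counts = {c: int(round(config.class_fractions.get(c, 0.0) * n)) for c in CLASS_LABELS}
    counts["stable"] += n - sum(counts.values())  # absorb rounding remainder
    if config.class_fractions.get("histone", 0) > 0:
        counts["histone"] = max(counts["histone"], 1)  # ruler needs an anchor
        counts["stable"] = n - sum(v for k, v in counts.items() if k != "stable")
    if counts["stable"] < 0:
        raise ValueError("class fractions leave no room for stable proteins")
    return counts


def _condition_effect(label: str, genotype: str, treatment: str,
                      config: SimulationConfig, is_receptor: bool) -> float:
    """Mean log2 offset for a protein class in one condition."""
    if treatment == config.treatments[0]:
        return 0.0
    if label in ("autophagy_client", "known_fluxer"):
        eff = config.client_effect
        if is_receptor:
            eff *= config.receptor_effect_scale
        if genotype != config.genotypes[0]:
            eff *= 1.0 - config.rescue_fraction
        return eff
    if label == "translation_suppressed":
        return config.suppression_effect
    return 0.0


def simulate_quant(
    config: SimulationConfig, seed: int | None = None
) -> tuple[QuantExperiment, pd.DataFrame, GroundTruth]:
    """Simulate a quant experiment, its annotations, and the planted truth.

    Intensities are ``copies x 2**(condition effect + noise)``; the result is
    deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = _class_counts(config)

    labels, ids = [], []
    for cls in CLASS_LABELS:
        for i in range(counts[cls]):
            ids.append(f"{cls.upper()[:4]}{i:05d}")
            labels.append(cls)
    labels = pd.Series(labels, index=pd.Index(ids, name="protein_id"), name="class")

    lo, hi = config.copies_log10_range
    copies = pd.Series(
        10.0 ** rng.uniform(lo, hi, size=len(ids)), index=labels.index,
        name="true_copies",
    )

    ann = _simulate_annotations(labels, rng, config)

    # Anchor histone mass to DNA mass so the ruler is absolutely calibrated.
    hist = labels == "histone"
    if hist.any():
        hist_mass_g = (copies[hist] * ann.loc[hist.index[hist], "molar_mass"]).sum() / Avogadro
        target_g = config.histone_dna_mass_ratio * config.dna_mass_pg * 1e-12
        copies[hist] *= target_g / hist_mass_g

    # Planted receptors: Golgi-membrane clients with amplified turnover.
    golgi_mem_clients = labels.index[
        (labels == "autophagy_client")
        & (ann["golgi_class"] == "membrane").reindex(labels.index, fill_value=False)
    ]
    receptors = list(golgi_mem_clients[: config.n_receptors])

    design = _make_design(config)
    effects = np.zeros((len(labels), len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        for i, (pid, cls) in enumerate(labels.items()):
            effects[i, j] = _condition_effect(
                cls, row.genotype, row.treatment, config, pid in receptors
            )
    noise = rng.normal(0.0, config.noise_sd, size=effects.shape) if config.noise_sd > 0 \
        else np.zeros_like(effects)
    intensity = pd.DataFrame(
        copies.to_numpy()[:, None] * 2.0 ** (effects + noise),
        index=labels.index, columns=design["channel_id"].tolist(),
    )
    exp = QuantExperiment(intensity=intensity, design=design)
    truth = GroundTruth(labels=labels, true_copies=copies, receptors=receptors)
    return exp, ann, truth


def _simulate_annotations(labels: pd.Series, rng: np.random.Generator,
                          config: SimulationConfig) -> pd.DataFrame:
    comp = pd.Series(index=labels.index, dtype=object)
    for cls, mix in config.compartment_mixture.items():
        idx = labels.index[labels == cls]
        if len(idx) == 0:
            continue
        cats = list(mix)
        probs = np.asarray([mix[c] for c in cats], dtype=float)
        comp[idx] = rng.choice(cats, size=len(idx), p=probs / probs.sum())
    comp = comp.fillna("other")

    golgi_class = pd.Series("not_golgi", index=labels.index, dtype=object)
    tm = pd.Series(0, index=labels.index, dtype=int)
    for cls in labels.unique():
        idx = labels.index[(labels == cls) & (comp == "Golgi")]
        if len(idx) == 0:
            continue
        p_mem = _GOLGI_MEMBRANE_PROB.get(cls, _GOLGI_MEMBRANE_PROB_DEFAULT)
        is_mem = rng.random(len(idx)) < p_mem
        golgi_class[idx] = np.where(is_mem, "membrane", "associated")
        tm[idx[is_mem]] = rng.integers(1, 8, size=int(is_mem.sum()))

    molar_mass = 10.0 ** rng.uniform(4.3, 5.3, size=len(labels))  # ~20-200 kDa
    molar_mass[(labels == "histone").to_numpy()] = 1.4e4 * (
        1.0 + 0.1 * rng.random(int((labels == "histone").sum()))
    )
    ann = pd.DataFrame(
        {
            "compartment": comp,
            "golgi_class": golgi_class,
            "tm_count": tm,
            "known_fluxer": labels == "known_fluxer",
            "histone": labels == "histone",
            "molar_mass": molar_mass,
        }
    )
    return validate_annotations(ann)


def simulate_peptides(
    exp: QuantExperiment,
    truth: GroundTruth,
    ann: pd.DataFrame,
    mean_peptides: float = 4.0,
    ms1_noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a peptide table consistent with the quant experiment.

    Each protein yields ``1 + Poisson(mean_peptides - 1)`` peptides.  A
    protein's total MS1 area is proportional to its summed channel amount
    times molar mass (MS1 integrates material from every multiplexed sample),
    split across its peptides; per-channel reporter intensities follow the
    protein's channel profile, so summed apportioned MS1 signal is
    proportional to untreated copies x molar mass up to noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    scale = 1e-6  # arbitrary instrument response
    for pid in exp.proteins:
        n_pep = 1 + rng.poisson(max(mean_peptides - 1.0, 0.0))
        profile = exp.intensity.loc[pid]
        total_area = scale * ann.loc[pid, "molar_mass"] * float(profile.sum())
        if ms1_noise_sd > 0:
            total_area *= 2.0 ** rng.normal(0.0, ms1_noise_sd)
        fracs = rng.dirichlet(np.ones(n_pep)) if n_pep > 1 else np.array([1.0])
        for j in range(n_pep):
            row = {"peptide_id": f"{pid}_p{j}", "protein_id": pid,
                   "ms1_area": total_area * fracs[j]}
            for ch in exp.channels:
                row[ch] = float(profile[ch]) * fracs[j]
            rows.append(row)
    pep = pd.DataFrame(rows)
    dropped = set(exp.proteins) - set(pep["protein_id"])
    if dropped:
        logger.info("%d protein(s) yielded zero peptides", len(dropped))
    return pep


def simulate_proximity(
    truth: GroundTruth,
    receptor_effect: float = 2.0,
    lds_rescue: float = 1.0,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int | None = None,
    experiment_id: str = "sim_proximity",
) -> QuantExperiment:
    """Simulate an ATG8-proximity labelling experiment.

    Planted receptors are enriched in starved WT-ATG8 channels by
    ``receptor_effect`` (log2); the enrichment is reduced by ``lds_rescue``
    in the LIR-docking-site mutant channels.  Bystanders are flat.
    """
    if not 0.0 <= lds_rescue <= 1.0:
        raise ValueError("lds_rescue must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    design = pd.DataFrame(
        [
            dict(channel_id=f"{g}_{t}_r{r}", genotype=g, treatment=t,
                 replicate=r, experiment_id=experiment_id)
            for g in ("ATG8_WT", "ATG8_LDS")
            for t in ("UT", "EBSS_BafA1")
            for r in range(1, n_replicates + 1)
        ]
    )
    ids = truth.labels.index
    baseline = 10.0 ** rng.uniform(3.0, 6.0, size=len(ids))
    is_rec = ids.isin(truth.receptors)
    effects = np.zeros((len(ids), len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        if row.treatment == "EBSS_BafA1":
            eff = receptor_effect
            if row.genotype == "ATG8_LDS":
                eff *= 1.0 - lds_rescue
            effects[is_rec, j] = eff
    noise = rng.normal(0.0, noise_sd, size=effects.shape) if noise_sd > 0 \
        else np.zeros_like(effects)
    intensity = pd.DataFrame(
        baseline[:, None] * 2.0 ** (effects + noise),
        index=ids, columns=design["channel_id"].tolist(),
    )
    return QuantExperiment(intensity=intensity, design=design)
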