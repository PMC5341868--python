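"""Synthetic data with the statistical structure of a paired CRC miRNA study.

The generator emulates a miRNA microarray over paired normal / adenoma /
carcinoma colon tissue: a configurable number of miRNAs measured on the
log2 scale, a planted set of up- and down-regulated species, and a latent
factor that couples miR-155 to the miR-143/145/192/378 group with a
correlation whose sign flips between normal and tumour tissue.  Everything
downstream of the generator (differential calling, enrichment, synergy
networks, association statistics) can therefore be exercised and validated
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "AnnotationBundle",
    "ExpressionMatrix",
    "TISSUE_CLASSES",
    "HUB_MIRNA",
    "DEFAULT_CORR_GROUP",
    "simulate_expression",
    "simulate_annotations",
    "simulate_positivity",
]

TISSUE_CLASSES = ("normal", "adenoma", "carcinoma")

#: The miRNA around which the synergy structure is organised.
HUB_MIRNA = "miR-155"

#: miRNAs sharing a latent factor with miR-155 (negatively coupled in
#: normal tissue, positively in tumour tissue).
DEFAULT_CORR_GROUP = ("miR-143", "miR-145", "miR-192", "miR-378")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A log2 expression matrix plus per-sample metadata.

    Attributes
    ----------
    values
        miRNAs (rows) by samples (columns), log2 scale.
    samples
        Indexed by sample id, with columns ``tissue_class`` and ``pair_id``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample metadata disagree")
        bad = set(self.samples["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue classes: {sorted(bad)}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate miRNA ids: {list(dup)}")
        per = self.samples.groupby(["pair_id", "tissue_class"]).size()
        if (per > 1).any():
            key = per[per > 1].index[0]
            raise ValueError(f"pair {key[0]} has multiple {key[1]} samples")

    @property
    def mirnas(self) -> list[str]:
        return list(self.values.index)

    def class_samples(self, tissue_class: str) -> list[str]:
        """Sample ids belonging to one tissue class, in pair order."""
        sub = self.samples[self.samples["tissue_class"] == tissue_class]
        return list(sub.sort_values("pair_id").index)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic miRNA array.

    Defaults reproduce the array scale of the motivating study: 830 human
    miRNAs over six pairs each of normal, adenoma and carcinoma tissue,
    with 40 planted up-regulated and 8 planted down-regulated miRNAs at an
    absolute log2 fold change of 1.5 against Gaussian noise of SD 0.3.
    """

    n_mirnas: int = 830
    n_pairs: int = 6
    n_up: int = 40
    n_down: int = 8
    effect_log2fc: float = 1.5
    #: Adenoma receives this fraction of the carcinoma effect (partial,
    #: "initial" deregulation on the normal->adenoma->carcinoma axis).
    adenoma_effect_fraction: float = 0.5
    noise_sd: float = 0.3
    corr_group: tuple[str, ...] = DEFAULT_CORR_GROUP
    #: Magnitude of the within-class correlation induced between miR-155
    #: and each corr_group member (latent-factor coupling strength).
    corr_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or self.n_pairs <= 0:
            raise ValueError("n_mirnas and n_pairs must be positive")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_up + self.n_down > self.n_mirnas:
            raise ValueError("n_up + n_down exceeds n_mirnas")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.corr_strength < 1:
            raise ValueError("corr_strength must lie in [0, 1)")
        if not 0 <= self.adenoma_effect_fraction <= 1:
            raise ValueError("adenoma_effect_fraction must lie in [0, 1]")
        group = tuple(self.corr_group)
        if len(set(group)) != len(group) or HUB_MIRNA in group:
            raise ValueError("corr_group must be distinct miRNAs other than miR-155")
        if self.n_mirnas < 1 + len(group):
            raise ValueError("n_mirnas too small to hold miR-155 and corr_group")
        object.__setattr__(self, "corr_group", group)

    def mirna_labels(self) -> list[str]:
        """Deterministic label list: miR-155, the correlated group, then fillers."""
        n_fill = self.n_mirnas - 1 - len(self.corr_group)
        fillers = [f"miR-sim-{i:04d}" for i in range(1, n_fill + 1)]
        return [HUB_MIRNA, *self.corr_group, *fillers]


def _child_rng(seed: int, key: int) -> np.random.Generator:
    # Named child streams off one root seed: adding a stream never
    # perturbs draws taken from the others.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def planted_sets(config: SimulationConfig) -> tuple[set[str], set[str]]:
    """The planted up- and down-regulated miRNA labels for a config.

    miR-155 is always the first up-regulated miRNA (when ``n_up`` >= 1)
    and the correlated group fills the down-regulated set first, matching
    the direction each is reported to move in carcinoma tissue.  Remaining
    slots are drawn uniformly from the filler miRNAs.
    """
    labels = config.mirna_labels()
    rng = _child_rng(config.seed, 1)
    up: list[str] = [HUB_MIRNA] if config.n_up >= 1 else []
    down: list[str] = list(config.corr_group[: config.n_down])
    taken = set(up) | set(down)
    pool = [m for m in labels if m not in taken]
    need_up, need_down = config.n_up - len(up), config.n_down - len(down)
    extra = rng.choice(len(pool), size=need_up + need_down, replace=False)
    up += [pool[i] for i in extra[:need_up]]
    down += [pool[i] for i in extra[need_up:]]
    return set(up), set(down)


def _correlated_noise(corr: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw p rows of k unit-variance observations with correlation ``corr``.

    When the sample size allows (k > p), the draw is *empirically exact*:
    rows are centred and whitened so their sample correlation equals
    ``corr`` to machine precision — the ``mvrnorm(empirical=TRUE)``
    convention.  With six samples per tissue class this makes the planted
    coupling strength an exact in-sample property rather than a noisy
    population target, and keeps the latent factor out of paired class
    means.  For k <= p a plain Cholesky draw is used instead.
    """
    p = corr.shape[0]
    chol = np.linalg.cholesky(corr)
    x = rng.standard_normal((p, k))
    if k <= p:
        return chol @ x
    x = x - x.mean(axis=1, keepdims=True)
    u, _, vt = np.linalg.svd(x, full_matrices=False)
    return chol @ (math.sqrt(k - 1) * u @ vt)


def simulate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Generate a paired log2 expression matrix under the planted model.

    The model for miRNA *i* in sample *j* (class *c*, pair *p*) is::

        x_ij = baseline_i + delta_i(c) + noise_sd * e_ij

    with per-miRNA baselines uniform on [4, 12], ``delta`` equal to
    +/- effect_log2fc in carcinoma (scaled by ``adenoma_effect_fraction``
    in adenoma) for planted miRNAs and 0 otherwise, and ``e`` standard
    Gaussian noise.  For miR-155 and the correlated group the noise is a
    single-factor multivariate Gaussian with within-class correlation
    ``s_i * s_j * corr_strength``, where the loading sign ``s`` is
    negative only for miR-155 in normal tissue — producing the
    negative-in-normal, positive-in-tumour coupling with each group
    member.  With enough samples per class the draw is empirically exact
    (see :func:`_correlated_noise`), so planted fold changes are
    recovered at the same power as for uncorrelated miRNAs.
    """
    labels = config.mirna_labels()
    n, k = config.n_mirnas, config.n_pairs
    sample_ids = [f"{c}_{p:02d}" for c in TISSUE_CLASSES for p in range(1, k + 1)]
    samples = pd.DataFrame(
        {
            "tissue_class": [c for c in TISSUE_CLASSES for _ in range(k)],
            "pair_id": [f"P{p:02d}" for _ in TISSUE_CLASSES for p in range(1, k + 1)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    baseline = _child_rng(config.seed, 0).uniform(4.0, 12.0, size=n)
    up, down = planted_sets(config)
    direction = np.array([1.0 if m in up else -1.0 if m in down else 0.0 for m in labels])
    class_scale = {"normal": 0.0, "adenoma": config.adenoma_effect_fraction, "carcinoma": 1.0}

    noise = _child_rng(config.seed, 2).standard_normal((n, 3 * k))
    rng_latent = _child_rng(config.seed, 3)
    quintet = [HUB_MIRNA, *config.corr_group]
    rows = [labels.index(m) for m in quintet]
    rho = config.corr_strength
    for ci, c in enumerate(TISSUE_CLASSES):
        # Sign vector of the latent loading: miR-155 couples negatively to
        # the group in normal tissue, positively in tumour tissue.
        sign = np.ones(len(quintet))
        if c == "normal":
            sign[0] = -1.0
        corr = (1.0 - rho) * np.eye(len(quintet)) + rho * np.outer(sign, sign)
        cols = slice(ci * k, (ci + 1) * k)
        noise[rows, cols] = _correlated_noise(corr, k, rng_latent)

    values = np.empty((n, 3 * k))
    for ci, c in enumerate(TISSUE_CLASSES):
        cols = slice(ci * k, (ci + 1) * k)
        delta = direction * config.effect_log2fc * class_scale[c]
        values[:, cols] = baseline[:, None] + delta[:, None] + config.noise_sd * noise[:, cols]

    expr = pd.DataFrame(values, index=pd.Index(labels, name="mirna"), columns=sample_ids)
    return ExpressionMatrix(values=expr, samples=samples)


@dataclass(frozen=True)
class AnnotationBundle:
    """miRNA target map, pathway gene sets and TF->miRNA regulation table."""

    target_map: dict[str, set[str]]
    pathway_db: dict[str, set[str]]
    tf_map: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, mapping in (
            ("target_map", self.target_map),
            ("pathway_db", self.pathway_db),
            ("tf_map", self.tf_map),
        ):
            for key, val in mapping.items():
                if not val:
                    raise ValueError(f"{name}[{key!r}] is empty")

    @property
    def universe(self) -> set[str]:
        """Union of all pathway genes — the default enrichment universe."""
        out: set[str] = set()
        for genes in self.pathway_db.values():
            out |= genes
        return out


def simulate_annotations(
    config: SimulationConfig,
    n_genes: int = 400,
    n_pathways: int = 20,
    seed: int = 0,
    n_annotated: int = 30,
    n_partners: int = 8,
) -> AnnotationBundle:
    """Generate annotation tables with a guaranteed synergy structure.

    miR-155 is wired as a hub: for each of ``n_partners`` partner miRNAs
    (the correlated group first, then fillers) a dedicated pathway is
    chosen whose full gene set is planted into both miR-155's and that
    partner's target list, so each pair is guaranteed to share at least
    one strongly enriched pathway while the partners share none among
    themselves.  The TF table always contains SMAD3->miR-155,
    SMAD4->miR-155 and CEBPB->miR-143, the regulators reported for those
    host genes, plus random TF->miRNA-pair edges.

    Raises ``ValueError`` when the hub construction is infeasible for the
    requested sizes instead of silently dropping the guarantee.
    """
    if n_genes <= 0 or n_pathways <= 0:
        raise ValueError("n_genes and n_pathways must be positive")
    labels = config.mirna_labels()
    n_annotated = min(n_annotated, len(labels))
    annotated = labels[:n_annotated]
    partners = [m for m in annotated if m != HUB_MIRNA][:n_partners]
    if len(partners) < n_partners:
        raise ValueError("not enough annotated miRNAs to build the requested hub")
    if n_pathways < n_partners:
        raise ValueError(
            f"hub construction infeasible: {n_partners} partner pathways "
            f"requested but only {n_pathways} pathways available"
        )
    max_pathway = min(30, max(5, n_genes // 4))
    if n_genes < max_pathway:
        raise ValueError("n_genes smaller than the largest pathway size")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    pathway_db: dict[str, set[str]] = {}
    for p in range(1, n_pathways + 1):
        size = int(rng.integers(8, max_pathway + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        pathway_db[f"path{p:04d}"] = {genes[g] for g in members}

    pathway_ids = sorted(pathway_db)
    target_map: dict[str, set[str]] = {}
    hub_targets: set[str] = set()
    for i, partner in enumerate(partners):
        core = set(pathway_db[pathway_ids[i]])
        extra = {genes[g] for g in rng.choice(n_genes, size=8, replace=False)}
        target_map[partner] = core | extra
        hub_targets |= core
    target_map[HUB_MIRNA] = hub_targets | {
        genes[g] for g in rng.choice(n_genes, size=8, replace=False)
    }
    for m in annotated:
        if m not in target_map:
            size = int(rng.integers(15, 40))
            target_map[m] = {genes[g] for g in rng.choice(n_genes, size=size, replace=False)}

    tf_map: dict[str, set[str]] = {
        "SMAD3": {HUB_MIRNA},
        "SMAD4": {HUB_MIRNA},
        "CEBPB": {"miR-143"} if "miR-143" in labels else {partners[0]},
        # a co-regulator of miR-155 and the down-regulated group, so the
        # TF-based synergy network links the quintet
        "NFKB1": {HUB_MIRNA, *(m for m in config.corr_group if m in annotated)},
    }
    pool = [m for m in annotated]
    for t in range(1, 6):
        pair = rng.choice(len(pool), size=2, replace=False)
        tf_map[f"TF{t:02d}"] = {pool[pair[0]], pool[pair[1]]}
    return AnnotationBundle(target_map=target_map, pathway_db=pathway_db, tf_map=tf_map)


def simulate_positivity(n: int, p_exposure: float, odds_ratio: float, seed: int = 0):
    """Draw an n-subject 2x2 positivity table with a requested odds ratio.

    Subjects carry a binary exposure (e.g. TGF-beta1 positivity) with
    marginal ``p_exposure``; marker positivity is Bernoulli with
    ``logit P(marker | exposure) = +/- log(odds_ratio) / 2`` — a symmetric
    parameterisation whose conditional odds ratio equals ``odds_ratio``
    exactly and whose marker marginal is 1/2 at the null.  Returns a
    :class:`~mirsynergy.association.ContingencyTable2x2` in the layout
    a = exposure+/marker+, b = exposure-/marker+, c = exposure+/marker-,
    d = exposure-/marker-.
    """
    from .association import ContingencyTable2x2

    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p_exposure < 1:
        raise ValueError("p_exposure must lie strictly in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(20,)))
    exposure = rng.random(n) < p_exposure
    half = 0.5 * math.log(odds_ratio)
    p_marker = 1.0 / (1.0 + np.exp(-np.where(exposure, half, -half)))
    marker = rng.random(n) < p_marker
    a = int(np.sum(exposure & marker))
    b = int(np.sum(~exposure & marker))
    c = int(np.sum(exposure & ~marker))
    d = int(np.sum(~exposure & ~marker))
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def positivity_cell_probabilities(p_exposure: float, odds_ratio: float) -> np.ndarray:
    """Exact cell probabilities [[a, b], [c, d]] of the positivity sampler."""
    if not 0 < p_exposure < 1:
        raise ValueError("p_exposure must lie strictly in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    half = 0.5 * math.log(odds_ratio)
    p1 = 1.0 / (1.0 + math.exp(-half))
    p0 = 1.0 / (1.0 + math.exp(half))
    return np.array(
        [
            [p_exposure * p1, (1 - p_exposure) * p0],
            [p_exposure * (1 - p1), (1 - p_exposure) * (1 - p0)],
        ]
    )
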