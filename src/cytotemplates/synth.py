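"""Synthetic cohorts with the statistical structure the pipeline assumes.

Samples are finite mixtures of well-separated multivariate Gaussians (the
model class underlying the Gaussian cluster summaries), with hierarchical
mean shifts emulating the three sources of variation in a longitudinal
healthy-donor study — technical/replicate, day-to-day, and between-subject
biological variation — and a disease cohort in which a minority class
carries extra "blast-like" populations absent from the majority class.

Every generated dataset carries ground-truth labels at the population,
sample, and class level, so downstream stages can be tested by parameter
recovery. All randomness flows through one ``numpy.random.default_rng``
seeded generator per cohort; a fixed seed reproduces the cohort bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CohortMetadata, EventMatrix

__all__ = [
    "PopulationSpec",
    "simulate_sample",
    "simulate_hd_cohort",
    "simulate_disease_cohort",
    "hd_default_populations",
    "disease_shared_populations",
    "disease_blast_population",
    "HDCohort",
    "DiseaseCohort",
]

WEIGHT_CONCENTRATION = 200.0  # Dirichlet concentration for abundance jitter


@dataclass
class PopulationSpec:
    """Generative description of one cell population."""

    mean: np.ndarray
    covariance: np.ndarray
    expected_fraction: float
    presence_prob: float = 1.0
    tag: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if not 0 < self.expected_fraction <= 1:
            raise ValueError("expected_fraction must be in (0, 1]")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")


def simulate_sample(
    populations: list[PopulationSpec],
    n_cells: int,
    rng: np.random.Generator,
    shifts: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    sample_id: str = "sample",
    t_dof: float | None = None,
) -> tuple[EventMatrix, np.ndarray]:
    """Draw one sample from a Gaussian mixture with per-population shifts.

    Population presence is Bernoulli(presence_prob) (resampled if nothing
    is present); abundances are Dirichlet-jittered around the expected
    fractions of the present populations; ``shifts`` (one vector per
    population) move the means, emulating batch structure. Returns the
    event matrix plus the true population index of every cell.
    ``t_dof`` switches to a multivariate t with that many degrees of
    freedom for heavy-tailed robustness probes.
    """
    n_pop = len(populations)
    p = populations[0].mean.shape[0]
    if shifts is None:
        shifts = np.zeros((n_pop, p))
    shifts = np.asarray(shifts, dtype=float).reshape(n_pop, p)

    present = np.array([rng.random() < pop.presence_prob for pop in populations])
    while not present.any():
        present = np.array([rng.random() < pop.presence_prob for pop in populations])

    fractions = np.array(
        [pop.expected_fraction if ok else 0.0 for pop, ok in zip(populations, present)]
    )
    fractions /= fractions.sum()
    alive = np.flatnonzero(fractions > 0)
    weights = np.zeros(n_pop)
    weights[alive] = rng.dirichlet(WEIGHT_CONCENTRATION * fractions[alive])
    counts = rng.multinomial(n_cells, weights)

    blocks, labels = [], []
    for idx in range(n_pop):
        if counts[idx] == 0:
            continue
        pop = populations[idx]
        mean = pop.mean + shifts[idx]
        draw = rng.multivariate_normal(mean, pop.covariance, size=counts[idx])
        if t_dof is not None:
            g = rng.chisquare(t_dof, size=counts[idx]) / t_dof
            draw = mean + (draw - mean) / np.sqrt(g)[:, None]
        blocks.append(draw)
        labels.append(np.full(counts[idx], idx))
    values = np.vstack(blocks)
    truth = np.concatenate(labels)
    perm = rng.permutation(values.shape[0])
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(p)]
    return (
        EventMatrix(values[perm], list(channel_names), sample_id),
        truth[perm],
    )


# --- healthy-donor cohort --------------------------------------------------

HD_CHANNELS = ["CD45", "CD3", "CD4", "CD8", "CD19"]


def hd_default_populations() -> list[PopulationSpec]:
    """Four lymphocyte populations in five channels, unit covariance,
    pairwise mean separation >= 10 sigma: helper T, cytotoxic T, B, NK."""
    eye = np.eye(5)
    return [
        PopulationSpec([10, 10, 10, 0, 0], eye, 0.35, tag="helper_T"),
        PopulationSpec([10, 10, 0, 10, 0], eye, 0.25, tag="cytotoxic_T"),
        PopulationSpec([10, 0, 0, 0, 10], eye, 0.20, tag="B"),
        PopulationSpec([10, 0, 0, 0, 0], eye, 0.20, tag="NK"),
    ]


@dataclass
class HDCohort:
    samples: list[EventMatrix]
    truths: list[np.ndarray]
    metadata: CohortMetadata
    populations: list[PopulationSpec] = field(default_factory=list)


def simulate_hd_cohort(
    seed: int = 0,
    n_subjects: int = 5,
    days_per_subject: tuple[int, ...] | int = (4, 3, 2, 2, 2),
    n_replicates: int = 5,
    n_cells: int = 1000,
    subject_sd: float = 2.0,
    day_sd: float = 0.5,
    replicate_sd: float = 0.1,
    populations: list[PopulationSpec] | None = None,
) -> HDCohort:
    """Longitudinal healthy-donor cohort: subjects x days x replicates.

    The default (5 subjects with 4,3,2,2,2 sampling days and 5 technical
    replicates each) yields 65 samples. Per-population mean shifts are
    drawn independently at each hierarchy level with standard deviations
    subject_sd >> day_sd >> replicate_sd, so subject identity dominates the
    between-sample structure and is recoverable from the template tree.
    """
    rng = np.random.default_rng(seed)
    pops = populations if populations is not None else hd_default_populations()
    p = pops[0].mean.shape[0]
    n_pop = len(pops)
    channels = HD_CHANNELS if p == 5 else [f"ch{i}" for i in range(p)]
    if isinstance(days_per_subject, int):
        days_per_subject = tuple([days_per_subject] * n_subjects)
    if len(days_per_subject) != n_subjects:
        raise ValueError("need one day count per subject")

    samples: list[EventMatrix] = []
    truths: list[np.ndarray] = []
    meta = CohortMetadata()
    for s in range(n_subjects):
        subject = chr(ord("A") + s) if s < 26 else f"S{s}"
        subj_shift = rng.normal(0.0, subject_sd, size=(n_pop, p))
        for day in range(days_per_subject[s]):
            day_shift = rng.normal(0.0, day_sd, size=(n_pop, p))
            for rep in range(n_replicates):
                rep_shift = rng.normal(0.0, replicate_sd, size=(n_pop, p))
                sid = f"{subject}_d{day + 1}_r{rep + 1}"
                em, truth = simulate_sample(
                    pops,
                    n_cells,
                    rng,
                    shifts=subj_shift + day_shift + rep_shift,
                    channel_names=channels,
                    sample_id=sid,
                )
                samples.append(em)
                truths.append(truth)
                meta.add(sid, class_label=subject, subject=subject,
                         day=str(day + 1), replicate=str(rep + 1))
    return HDCohort(samples, truths, meta, pops)


# --- disease cohort --------------------------------------------------------

DISEASE_CHANNELS = ["FS", "SS", "CD45", "M1", "M2", "M3", "M4"]


def disease_shared_populations() -> list[PopulationSpec]:
    """Three populations common to both classes (7 channels, unit cov)."""
    eye = np.eye(7)
    return [
        PopulationSpec([0, 0, 10, 10, 0, 0, 0], eye, 0.40, tag="lymphocyte"),
        PopulationSpec([8, 8, 10, 0, 10, 0, 0], eye, 0.35, tag="monocyte"),
        PopulationSpec([14, 4, 10, 0, 0, 10, 0], eye, 0.25, tag="granulocyte"),
    ]


def disease_blast_population(fraction: float) -> PopulationSpec:
    """A blast-like population (medium scatter/CD45, disease marker high)
    at >= 5 sigma from every shared population."""
    return PopulationSpec(
        [6, 6, 5, 0, 0, 0, 10], np.eye(7), fraction, tag="blast"
    )


@dataclass
class DiseaseCohort:
    samples: list[EventMatrix]
    truths: list[np.ndarray]
    metadata: CohortMetadata
    train_ids: list[str]
    test_ids: list[str]
    blast_means: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_disease_cohort(
    seed: int = 0,
    n_negative: int = 200,
    n_positive: int = 30,
    n_cells: int = 1000,
    blast_fraction_range: tuple[float, float] = (0.2, 0.6),
    negative_shift_sd: float = 0.3,
    positive_shift_sd: float = 0.6,
    train_fraction: float = 0.5,
) -> DiseaseCohort:
    """Two-class cohort: shared populations plus minority-class blasts.

    Negative samples carry only the shared populations; every positive
    sample additionally carries a blast-like population at 20-60%
    abundance (mirroring the diagnostic blast-count threshold). Positive
    samples receive per-sample mean shifts with twice the standard
    deviation of the negatives, making the disease class the more
    heterogeneous one. Returns a stratified train/test split.
    """
    rng = np.random.default_rng(seed)
    shared = disease_shared_populations()
    p = shared[0].mean.shape[0]

    samples: list[EventMatrix] = []
    truths: list[np.ndarray] = []
    meta = CohortMetadata()
    blast_means: dict[str, np.ndarray] = {}

    for i in range(n_negative):
        sid = f"neg{i:03d}"
        shifts = rng.normal(0.0, negative_shift_sd, size=(len(shared), p))
        em, truth = simulate_sample(
            shared, n_cells, rng, shifts=shifts,
            channel_names=DISEASE_CHANNELS, sample_id=sid,
        )
        samples.append(em)
        truths.append(truth)
        meta.add(sid, class_label="negative")

    lo, hi = blast_fraction_range
    for i in range(n_positive):
        sid = f"pos{i:03d}"
        frac = rng.uniform(lo, hi)
        blast = disease_blast_population(frac)
        pops = [
            PopulationSpec(
                s.mean, s.covariance,
                s.expected_fraction * (1.0 - frac), tag=s.tag,
            )
            for s in shared
        ] + [blast]
        shifts = rng.normal(0.0, positive_shift_sd, size=(len(pops), p))
        em, truth = simulate_sample(
            pops, n_cells, rng, shifts=shifts,
            channel_names=DISEASE_CHANNELS, sample_id=sid,
        )
        samples.append(em)
        truths.append(truth)
        meta.add(sid, class_label="positive")
        blast_means[sid] = blast.mean + shifts[-1]

    neg_ids = [s.sample_id for s in samples if meta.class_of(s.sample_id) == "negative"]
    pos_ids = [s.sample_id for s in samples if meta.class_of(s.sample_id) == "positive"]
    train_ids: list[str] = []
    test_ids: list[str] = []
    for ids in (neg_ids, pos_ids):
        order = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        train_ids.extend(ids[j] for j in order[:n_train])
        test_ids.extend(ids[j] for j in order[n_train:])
    return DiseaseCohort(samples, truths, meta, sorted(train_ids), sorted(test_ids),
                         blast_means)
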