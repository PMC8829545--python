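"""Synthetic multi-subject cytometry cohorts with known ground truth.

The generator emulates the structure of a mass-cytometry immunophenotyping
study: a small cohort of subjects split into clinical groups (elite
controllers and individuals treated during acute vs. chronic infection),
each contributing cells from one or two tissue compartments (blood, lymph
node). Cells arise from a finite set of latent populations; each
population has a per-marker normal expression profile on the arcsinh
scale, so that markers are bimodal across populations, as manual gating
assumes.

Population membership follows a multinomial-logit model::

    P(cell of subject i in group g belongs to population p)
        = softmax_p( base_logit_p
                     + u_i * [p enrichable]
                     + enrichment[(g, p)]
                     + compartment_shift[(c, p)] )

with a single subject-level random intercept ``u_i ~ N(0, subject_sd^2)``
applied to the designated "enrichable" populations. Binarizing membership
of one enrichable population therefore yields exactly the logistic
mixed model the enrichment fitter estimates, and the planted
``enrichment`` log odds ratios are the coefficients it must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .events import EventTable

__all__ = [
    "PopulationArchetype",
    "CohortSpec",
    "population_proportions",
    "generate_cohort",
]


@dataclass
class PopulationArchetype:
    """A latent cell population: per-marker normal profile plus abundance.

    ``mean_vector`` and ``sd_vector`` are on the arcsinh scale and must
    match the panel length; ``base_logit`` is the population's baseline
    log-odds of membership before subject and group effects.
    """

    name: str
    mean_vector: np.ndarray
    sd_vector: np.ndarray
    base_logit: float = 0.0

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.sd_vector = np.asarray(self.sd_vector, dtype=float)
        if self.mean_vector.shape != self.sd_vector.shape:
            raise ValueError(
                f"population {self.name!r}: mean_vector and sd_vector lengths differ"
            )
        if (self.sd_vector < 0).any():
            raise ValueError(f"population {self.name!r}: sd_vector entries must be >= 0")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Parameters
    ----------
    populations
        Latent populations; all must share one panel length.
    markers
        Marker names (length = panel size).
    groups
        Ordered clinical group labels.
    subjects_per_group
        Either one count for every group or a per-group mapping.
    cells_per_subject
        Cells drawn per subject and compartment.
    subject_sd
        SD of the per-subject random intercept on membership logits.
    enrichment
        Planted ``(group, population) -> log odds ratio`` effects.
    enrichable
        Populations the subject intercept applies to; defaults to the
        populations named in ``enrichment``. (A scalar added to *every*
        logit would cancel in the softmax, so the intercept must target a
        strict subset to produce subject-level abundance variation.)
    compartments
        Tissue compartments to generate; each subject contributes
        ``cells_per_subject`` cells per compartment.
    compartment_shift
        Planted ``(compartment, population) -> logit shift`` relative to
        the first compartment, giving paired blood-vs-LN effects.
    subject_effect
        ``"shared"`` (default): one scalar intercept per subject applied
        to the enrichable populations. ``"per_population"``: an
        independent N(0, subject_sd^2) intercept per subject and
        population, giving every cluster's binarized abundance its own
        subject-level dispersion (the structure the enrichment GLMM
        assumes for each cluster it tests).
    seed
        Seed for the single generator driving all sampling.
    """

    populations: list[PopulationArchetype]
    markers: list[str]
    groups: tuple[str, ...] = ("controller", "acute", "chronic")
    subjects_per_group: int | Mapping[str, int] = 5
    cells_per_subject: int = 2000
    subject_sd: float = 0.0
    enrichment: Mapping[tuple[str, str], float] = field(default_factory=dict)
    enrichable: Sequence[str] | None = None
    compartments: tuple[str, ...] = ("blood",)
    compartment_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    subject_effect: str = "shared"
    seed: int = 0

    def n_subjects(self, group: str) -> int:
        if isinstance(self.subjects_per_group, Mapping):
            return int(self.subjects_per_group[group])
        return int(self.subjects_per_group)

    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def enrichable_names(self) -> list[str]:
        if self.enrichable is not None:
            return list(self.enrichable)
        return sorted({pop for (_g, pop) in self.enrichment})

    def validate(self) -> None:
        names = self.population_names()
        if len(self.populations) < 2:
            raise ValueError("invariant violated: need >= 2 populations")
        if len(set(names)) != len(names):
            raise ValueError("invariant violated: population names must be unique")
        panel = len(self.markers)
        for p in self.populations:
            if len(p.mean_vector) != panel:
                raise ValueError(
                    f"invariant violated: population {p.name!r} mean_vector length "
                    f"{len(p.mean_vector)} != panel size {panel}"
                )
        for g in self.groups:
            if self.n_subjects(g) < 2:
                raise ValueError(
                    f"invariant violated: need >= 2 subjects per group (group {g!r})"
                )
        if self.cells_per_subject < 50:
            raise ValueError("invariant violated: cells_per_subject must be >= 50")
        if self.subject_sd < 0:
            raise ValueError("invariant violated: subject_sd must be >= 0")
        for (g, pop) in self.enrichment:
            if g not in self.groups:
                raise ValueError(f"invariant violated: enrichment group {g!r} unknown")
            if pop not in names:
                raise ValueError(f"invariant violated: enrichment population {pop!r} unknown")
        for (c, pop) in self.compartment_shift:
            if c not in self.compartments:
                raise ValueError(
                    f"invariant violated: compartment_shift compartment {c!r} unknown"
                )
            if pop not in names:
                raise ValueError(
                    f"invariant violated: compartment_shift population {pop!r} unknown"
                )
        for pop in self.enrichable_names():
            if pop not in names:
                raise ValueError(f"invariant violated: enrichable population {pop!r} unknown")
        if self.subject_effect not in ("shared", "per_population"):
            raise ValueError(
                "invariant violated: subject_effect must be 'shared' or 'per_population'"
            )


def _membership_logits(
    spec: CohortSpec, group: str, subject_intercept, compartment: str | None
) -> np.ndarray:
    logits = np.array([p.base_logit for p in spec.populations], dtype=float)
    enrichable = set(spec.enrichable_names())
    if np.ndim(subject_intercept) == 1:
        logits += np.asarray(subject_intercept, dtype=float)
    for j, p in enumerate(spec.populations):
        if np.ndim(subject_intercept) == 0 and p.name in enrichable:
            logits[j] += float(subject_intercept)
        logits[j] += spec.enrichment.get((group, p.name), 0.0)
        if compartment is not None:
            logits[j] += spec.compartment_shift.get((compartment, p.name), 0.0)
    return logits


def population_proportions(
    spec: CohortSpec,
    group: str,
    subject_intercept: float = 0.0,
    compartment: str | None = None,
) -> np.ndarray:
    """Model membership probabilities for one subject.

    Softmax of base logits plus the subject intercept (a scalar applied
    to the enrichable populations, or one value per population), the
    group's planted enrichment, and the compartment shift. Sums to one.
    """
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}; expected one of {spec.groups}")
    logits = _membership_logits(spec, group, subject_intercept, compartment)
    logits -= logits.max()  # numerical stability; softmax is shift-invariant
    w = np.exp(logits)
    return w / w.sum()


def generate_cohort(spec: CohortSpec) -> EventTable:
    """Draw a full synthetic cohort, reproducible from ``spec.seed``.

    Subject random intercepts are drawn once per subject and shared
    across that subject's compartments (the same donor is sampled in
    blood and LN). Returns an :class:`EventTable` with
    ``truth_population`` recording the latent membership of each cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pop_names = np.array(spec.population_names())
    means = np.vstack([p.mean_vector for p in spec.populations])
    sds = np.vstack([p.sd_vector for p in spec.populations])
    n_pop = len(spec.populations)

    blocks_values: list[np.ndarray] = []
    blocks_subject: list[np.ndarray] = []
    blocks_group: list[np.ndarray] = []
    blocks_comp: list[np.ndarray] = []
    blocks_truth: list[np.ndarray] = []

    for group in spec.groups:
        for j in range(spec.n_subjects(group)):
            subject = f"{group}-{j + 1:02d}"
            if spec.subject_effect == "per_population":
                u = rng.normal(0.0, spec.subject_sd, size=n_pop)
            else:
                u = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
            for comp in spec.compartments:
                probs = population_proportions(spec, group, u, comp)
                memb = rng.choice(n_pop, size=spec.cells_per_subject, p=probs)
                noise = rng.standard_normal((spec.cells_per_subject, len(spec.markers)))
                vals = means[memb] + noise * sds[memb]
                n = spec.cells_per_subject
                blocks_values.append(vals)
                blocks_subject.append(np.full(n, subject, dtype=object))
                blocks_group.append(np.full(n, group, dtype=object))
                blocks_comp.append(np.full(n, comp, dtype=object))
                blocks_truth.append(pop_names[memb])

    return EventTable(
        values=np.vstack(blocks_values),
        markers=list(spec.markers),
        subject_id=np.concatenate(blocks_subject),
        group=np.concatenate(blocks_group),
        compartment=np.concatenate(blocks_comp),
        truth_population=np.concatenate(blocks_truth),
    )
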