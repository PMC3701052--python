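"""Synthetic two-platform cytometry cohorts with known ground truth.

Emulates a paired platform-comparison design: the same healthy donors are
measured on two platforms (group A = conventional liquid reagents, group B =
lyophilized-reagent plates), in experimental triplicate, with a 9-marker
T-cell panel (CD3 plus the 8 lattice markers), a viability dye, and forward
scatter area/height.  Ground truth — every event's population label, marker
states, dead/doublet flags — is retained so downstream stages can be tested
without real data.

Generative model
----------------
* Event types: a small CD3-negative fraction; T cells split among named
  populations (defined by fixed CD4/CD8 states) plus an implicit background
  population taking the remaining frequency mass.
* Population frequencies: donor effects and replicate noise are additive on
  the log-ratio of each population to the background (a logistic-normal
  composition, the multivariate form of a logit-scale effect), so every
  draw stays on the simplex; platform effects multiply group-B frequencies
  and/or per-marker positivity rates.
* Marker states: fixed by the population pattern where specified, otherwise
  Bernoulli with a population-specific rate (donor logit shift, group
  ratio, replicate noise applied).
* Intensities: drawn directly on the arcsinh scale from a two-component
  normal mixture per marker; the separation is parameterized as a target
  stain index SI = (pos - neg location) / (2 x neg scale).  Raw-scale FCS
  output applies the inverse transform.
* Dead events stain bright on the viability channel; doublets double their
  scatter area while keeping height.

All distributional choices are stand-ins for undocumented real-data
behaviour; defaults are fixtures approximating a healthy-donor T-cell
compartment, not claims about any particular dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    Channel,
    EventMatrix,
    MARKER,
    SCATTER_AREA,
    SCATTER_HEIGHT,
    SampleMetadata,
    VIABILITY,
    metadata_frame,
)
from .lattice import DEFAULT_PANEL, NEUTRAL, NEG, POS, Phenotype
from .pregating import PregateConfig

GROUP_A = "CFP"
GROUP_B = "LFP"


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerIntensityModel:
    """Two-component normal mixture on the arcsinh scale."""

    neg_loc: float
    neg_scale: float
    pos_loc: float
    pos_scale: float

    def __post_init__(self):
        if self.neg_scale <= 0 or self.pos_scale <= 0:
            raise ValueError("component scales must be positive")

    @classmethod
    def from_stain_index(
        cls,
        stain_index: float,
        neg_loc: float = 0.4,
        neg_scale: float = 0.25,
        pos_scale: float = 0.45,
    ) -> "MarkerIntensityModel":
        """Separation chosen so SI = (pos_loc - neg_loc) / (2 * neg_scale)."""
        if stain_index <= 0:
            raise ValueError("stain index target must be positive")
        return cls(
            neg_loc=neg_loc,
            neg_scale=neg_scale,
            pos_loc=neg_loc + stain_index * 2.0 * neg_scale,
            pos_scale=pos_scale,
        )

    @property
    def target_stain_index(self) -> float:
        return (self.pos_loc - self.neg_loc) / (2.0 * self.neg_scale)

    @property
    def midpoint(self) -> float:
        return (self.pos_loc + self.neg_loc) / 2.0


@dataclass(frozen=True)
class PopulationSpec:
    """A generated cell population.

    ``states`` maps each panel marker to either a fixed boolean (the
    defining pattern) or a float positivity rate for markers the population
    leaves free.
    """

    name: str
    states: Mapping[str, "bool | float"]
    frequency: float  # baseline mean, as fraction of live T cells
    donor_sd: float = 0.15  # between-donor SD on the logit scale
    replicate_cv: float = 0.03  # within-donor multiplicative replicate CV

    def pattern(self) -> dict[str, bool]:
        return {m: v for m, v in self.states.items() if isinstance(v, bool)}

    def to_phenotype(self, panel: Sequence[str]) -> Phenotype:
        states = [NEUTRAL] * len(panel)
        for m, v in self.pattern().items():
            states[list(panel).index(m)] = POS if v else NEG
        return Phenotype(tuple(panel), tuple(states))


def _default_populations() -> tuple[PopulationSpec, ...]:
    return (
        PopulationSpec(
            name="cd4_t",
            states={"CD4": True, "CD8": False, "CD45RO": 0.45, "CD25": 0.10,
                    "Foxp3": 0.06, "IFNg": 0.12, "IL10": 0.02, "IL17A": 0.012},
            frequency=0.60,
        ),
        PopulationSpec(
            name="cd8_t",
            states={"CD4": False, "CD8": True, "CD45RO": 0.40, "CD25": 0.04,
                    "Foxp3": 0.010, "IFNg": 0.22, "IL10": 0.008,
                    "IL17A": 0.004},
            frequency=0.28,
        ),
    )


def _default_background() -> dict[str, "bool | float"]:
    # double-negative / gamma-delta-like remainder of the T compartment
    return {"CD4": False, "CD8": False, "CD45RO": 0.30, "CD25": 0.02,
            "Foxp3": 0.005, "IFNg": 0.05, "IL10": 0.005, "IL17A": 0.003}


#: default per-marker stain-index targets; mid-range values keep positive
#: locations realistic on the arcsinh scale
DEFAULT_STAIN_INDICES = {
    "CD3": 5.8, "CD4": 8.0, "CD8": 8.0, "CD45RO": 7.3, "CD25": 2.3,
    "Foxp3": 5.1, "IFNg": 8.0, "IL17A": 8.0, "IL10": 8.0,
}


def _default_intensity() -> dict[str, MarkerIntensityModel]:
    models = {
        m: MarkerIntensityModel.from_stain_index(si)
        for m, si in DEFAULT_STAIN_INDICES.items()
    }
    # viability: live cells are dull, dead cells stain bright
    models["Viability"] = MarkerIntensityModel(
        neg_loc=0.5, neg_scale=0.2, pos_loc=3.0, pos_scale=0.3
    )
    return models


def _default_platform_effects() -> dict[str, float]:
    # group-B / group-A frequency ratios: B detects more IL-10 (A reads 44%
    # lower), more IFN-g (A reads 20% lower), and elevated CD25 / Foxp3
    return {"IL10": 1.0 / 0.56, "IFNg": 1.25, "CD25": 1.6, "Foxp3": 1.8}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic two-group cohort."""

    n_donors: int = 12
    n_replicates: int = 3
    n_events_per_sample: int = 5000
    panel: tuple[str, ...] = DEFAULT_PANEL
    populations: tuple[PopulationSpec, ...] = field(
        default_factory=_default_populations
    )
    background_states: Mapping[str, "bool | float"] = field(
        default_factory=_default_background
    )
    platform_effects: Mapping[str, float] = field(
        default_factory=_default_platform_effects
    )
    intensity: Mapping[str, MarkerIntensityModel] = field(
        default_factory=_default_intensity
    )
    marker_rate_donor_sd: float = 0.10  # logit-scale donor SD on rates
    marker_rate_replicate_cv: float = 0.05
    dead_fraction: float = 0.05
    doublet_fraction: float = 0.03
    cd3_negative_fraction: float = 0.05
    groups: tuple[str, str] = (GROUP_A, GROUP_B)
    stimulation: str = "stimulated"
    timepoint: int = 1
    donor_prefix: str = "D"
    scatter_loc: float = 1.0e5
    scatter_scale: float = 1.2e4
    cofactor: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.n_events_per_sample < 1:
            raise ValueError("n_events_per_sample must be >= 1")
        if self.n_donors < 1 or self.n_replicates < 1:
            raise ValueError("n_donors and n_replicates must be >= 1")
        total = sum(p.frequency for p in self.populations)
        if not 0 <= total <= 1:
            raise ValueError(
                f"population frequencies must sum to <= 1, got {total}"
            )
        for p in self.populations:
            if not 0 <= p.frequency <= 1:
                raise ValueError(f"population {p.name!r}: frequency outside [0,1]")
            for m in p.states:
                if m not in self.panel:
                    raise ValueError(
                        f"population {p.name!r}: unknown marker {m!r}"
                    )
        for key, ratio in self.platform_effects.items():
            if ratio <= 0:
                raise ValueError(f"platform effect for {key!r} must be > 0")
        for frac_name in ("dead_fraction", "doublet_fraction",
                          "cd3_negative_fraction"):
            v = getattr(self, frac_name)
            if not 0 <= v < 1:
                raise ValueError(f"{frac_name} must be in [0, 1)")
        needed = set(self.panel) | {"CD3", "Viability"}
        missing = needed - set(self.intensity)
        if missing:
            raise ValueError(f"intensity model missing for {sorted(missing)}")

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations) + ("background",)

    def sample_id(self, donor: str, group: str, replicate: int) -> str:
        return f"{donor}_{group}_r{replicate}"


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-event labels and per-sample programmed frequencies."""

    panel: tuple[str, ...]
    events: dict[str, pd.DataFrame]  # sample_id -> per-event label table
    programmed: dict[str, dict[str, float]]  # sample_id -> pop -> frequency

    def _sample(self, sample_id: str) -> pd.DataFrame:
        if sample_id not in self.events:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.events[sample_id]

    def live_singlet_t(self, sample_id: str) -> pd.DataFrame:
        df = self._sample(sample_id)
        return df[df["is_t"] & ~df["dead"] & ~df["doublet"]]

    def denominator(self, sample_id: str) -> int:
        return int(len(self.live_singlet_t(sample_id)))

    def truth_frequency(self, sample_id: str, phenotype: Phenotype) -> float:
        """Fraction of live singlet T cells matching the phenotype pattern."""
        df = self.live_singlet_t(sample_id)
        mask = np.ones(len(df), dtype=bool)
        for marker, state in phenotype.specified().items():
            if marker not in df.columns:
                raise KeyError(
                    f"phenotype marker {marker!r} not in ground truth panel"
                )
            col = df[marker].to_numpy()
            mask &= col if state == POS else ~col
        denom = len(df)
        if denom == 0:
            raise ValueError(f"sample {sample_id!r} has no live singlet T cells")
        return float(mask.sum() / denom)

    def population_frequency(self, sample_id: str, name: str) -> float:
        """Realized frequency of a generated population (label recount)."""
        df = self.live_singlet_t(sample_id)
        if len(df) == 0:
            raise ValueError(f"sample {sample_id!r} has no live singlet T cells")
        return float((df["population"] == name).mean())

    def summary(self) -> dict:
        """JSON-serialisable per-sample truth summary."""
        out = {}
        for sample_id, df in self.events.items():
            live = self.live_singlet_t(sample_id)
            out[sample_id] = {
                "n_events": int(len(df)),
                "denominator": int(len(live)),
                "population_counts": {
                    str(k): int(v)
                    for k, v in live["population"].value_counts().items()
                },
                "marker_positive_counts": {
                    m: int(live[m].sum()) for m in self.panel
                },
                "programmed_frequencies": self.programmed[sample_id],
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray | float) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(x) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EventMatrix], pd.DataFrame, GroundTruth]:
    """Generate one donor x group x replicate sample grid.

    Donor effects are shared between the two groups (the same donor is run
    on both platforms), making the design paired.  Identical spec + seed
    give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    donors = [f"{spec.donor_prefix}{i + 1:02d}" for i in range(spec.n_donors)]
    group_a, group_b = spec.groups
    panel = list(spec.panel)

    # donor effects, drawn once in fixed order (shared across groups)
    pop_shift = {
        d: {p.name: rng.normal(0.0, p.donor_sd) for p in spec.populations}
        for d in donors
    }
    all_pops = list(spec.populations) + [
        PopulationSpec("background", spec.background_states, 0.0)
    ]
    rate_shift = {
        d: {
            (p.name, m): rng.normal(0.0, spec.marker_rate_donor_sd)
            for p in all_pops
            for m, v in p.states.items()
            if not isinstance(v, bool)
        }
        for d in donors
    }

    samples: list[EventMatrix] = []
    meta_rows: list[SampleMetadata] = []
    truth_events: dict[str, pd.DataFrame] = {}
    programmed: dict[str, dict[str, float]] = {}

    for donor in donors:
        for group in (group_a, group_b):
            for rep in range(1, spec.n_replicates + 1):
                sample_id = spec.sample_id(donor, group, rep)
                em, labels, freqs = _generate_sample(
                    spec, rng, sample_id, donor, group, is_group_b=(group == group_b),
                    pop_shift=pop_shift[donor], rate_shift=rate_shift[donor],
                )
                samples.append(em)
                truth_events[sample_id] = labels
                programmed[sample_id] = freqs
                meta_rows.append(
                    SampleMetadata(
                        sample_id=sample_id, donor=donor, group=group,
                        stimulation=spec.stimulation, replicate=rep,
                        timepoint=spec.timepoint, control=False,
                    )
                )

    metadata = metadata_frame(meta_rows)
    truth = GroundTruth(panel=spec.panel, events=truth_events,
                        programmed=programmed)
    return samples, metadata, truth


def _population_frequencies(
    spec: CohortSpec,
    rng: np.random.Generator,
    sample_id: str,
    is_group_b: bool,
    pop_shift: Mapping[str, float],
) -> dict[str, float]:
    """Donor and replicate variability act on the log-ratio of each
    population to the background (a logistic-normal composition), so the
    noisy vector always stays on the simplex; explicit platform-effect
    multipliers are applied afterwards and are the only way the total can
    overflow, which is reported as a config error naming the sample."""
    base = np.array([p.frequency for p in spec.populations])
    background = 1.0 - base.sum()
    eta = np.log(np.clip(base, 1e-12, None) / max(background, 1e-12))
    eta = eta + np.array([pop_shift[p.name] for p in spec.populations])
    eta = eta + np.array(
        [rng.normal(0.0, p.replicate_cv) for p in spec.populations]
    )
    expanded = np.exp(np.concatenate([eta, [0.0]]))
    simplex = expanded / expanded.sum()

    freqs = {}
    for p, f in zip(spec.populations, simplex[:-1]):
        f = float(f)
        if is_group_b:
            ratio = spec.platform_effects.get(p.name, 1.0)
            # a marker effect also scales populations whose pattern fixes
            # that marker positive
            for m, v in p.pattern().items():
                if v and m in spec.platform_effects:
                    ratio *= spec.platform_effects[m]
            f *= ratio
        freqs[p.name] = f
    total = sum(freqs.values())
    if total > 1:
        raise ValueError(
            f"sample {sample_id!r}: population frequencies sum to "
            f"{total:.4f} > 1 after effect multipliers"
        )
    freqs["background"] = 1.0 - total
    return freqs


def _marker_rates(
    spec: CohortSpec,
    rng: np.random.Generator,
    sample_id: str,
    is_group_b: bool,
    rate_shift: Mapping[tuple[str, str], float],
) -> dict[str, dict[str, float]]:
    """pop name -> marker -> positivity rate for this sample's free markers."""
    all_pops = list(spec.populations) + [
        PopulationSpec("background", spec.background_states, 0.0)
    ]
    out: dict[str, dict[str, float]] = {}
    for p in all_pops:
        rates = {}
        for m, v in p.states.items():
            if isinstance(v, bool):
                continue
            r = float(_expit(_logit(v) + rate_shift[(p.name, m)]))
            r *= float(np.exp(rng.normal(0.0, spec.marker_rate_replicate_cv)))
            if is_group_b:
                r *= spec.platform_effects.get(m, 1.0)
            if r >= 1:
                raise ValueError(
                    f"sample {sample_id!r}: rate for marker {m!r} in "
                    f"population {p.name!r} reaches {r:.3f} >= 1 after effects"
                )
            rates[m] = r
        out[p.name] = rates
    return out


def _generate_sample(
    spec: CohortSpec,
    rng: np.random.Generator,
    sample_id: str,
    donor: str,
    group: str,
    is_group_b: bool,
    pop_shift: Mapping[str, float],
    rate_shift: Mapping[tuple[str, str], float],
) -> tuple[EventMatrix, pd.DataFrame, dict[str, float]]:
    n = spec.n_events_per_sample
    panel = list(spec.panel)
    freqs = _population_frequencies(spec, rng, sample_id, is_group_b, pop_shift)
    rates = _marker_rates(spec, rng, sample_id, is_group_b, rate_shift)

    all_pops = {p.name: p for p in spec.populations}
    all_pops["background"] = PopulationSpec(
        "background", spec.background_states, 0.0
    )

    is_t = rng.random(n) >= spec.cd3_negative_fraction
    dead = rng.random(n) < spec.dead_fraction
    doublet = rng.random(n) < spec.doublet_fraction

    pop_names = list(freqs)
    probs = np.array([freqs[p] for p in pop_names])
    pop_idx = rng.choice(len(pop_names), size=n, p=probs / probs.sum())
    population = np.array(pop_names, dtype=object)[pop_idx]
    population[~is_t] = "non_t"

    # realized marker states
    states = np.zeros((n, len(panel)), dtype=bool)
    u = rng.random((n, len(panel)))
    for j, marker in enumerate(panel):
        col = np.zeros(n, dtype=bool)
        for name, p in all_pops.items():
            sel = population == name
            if not sel.any():
                continue
            v = p.states.get(marker, 0.0)
            if isinstance(v, bool):
                col[sel] = v
            else:
                col[sel] = u[sel, j] < rates[name].get(marker, float(v))
        # CD3-negative events: low background positivity on all markers
        sel = population == "non_t"
        col[sel] = u[sel, j] < 0.01
        states[:, j] = col

    # intensities on the arcsinh scale
    n_channels = 4 + len(panel)
    values = np.empty((n, n_channels), dtype=float)
    fsc = np.maximum(rng.normal(spec.scatter_loc, spec.scatter_scale, n), 1.0)
    singlet_ratio = rng.normal(1.05, 0.05, n)
    doublet_ratio = rng.normal(1.90, 0.12, n)
    ratio = np.clip(np.where(doublet, doublet_ratio, singlet_ratio), 0.5, None)
    values[:, 0] = fsc * np.where(doublet, 2.0, 1.0)  # FSC-A
    values[:, 1] = values[:, 0] / ratio  # FSC-H

    def mixture(model: MarkerIntensityModel, positive: np.ndarray) -> np.ndarray:
        loc = np.where(positive, model.pos_loc, model.neg_loc)
        scale = np.where(positive, model.pos_scale, model.neg_scale)
        return rng.normal(loc, scale)

    values[:, 2] = mixture(spec.intensity["Viability"], dead)
    values[:, 3] = mixture(spec.intensity["CD3"], is_t)
    for j, marker in enumerate(panel):
        values[:, 4 + j] = mixture(spec.intensity[marker], states[:, j])

    channels = [
        Channel("FSC-A", SCATTER_AREA),
        Channel("FSC-H", SCATTER_HEIGHT),
        Channel("Viability", VIABILITY),
        Channel("CD3", MARKER, marker="CD3"),
    ] + [Channel(m, MARKER, marker=m) for m in panel]
    cofactors = {c.name: spec.cofactor for c in channels
                 if c.role in (MARKER, VIABILITY)}
    em = EventMatrix(
        sample_id=sample_id, channels=channels, values=values,
        transform="arcsinh", cofactors=cofactors,
    )
    labels = pd.DataFrame(
        {"population": population, "is_t": is_t, "dead": dead,
         "doublet": doublet,
         **{m: states[:, j] for j, m in enumerate(panel)}}
    )
    return em, labels, freqs


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def default_pregate_config(
    spec: CohortSpec, min_live_cd4: int = 0
) -> PregateConfig:
    """Thresholds at the mixture midpoints of the generating model.

    ``min_live_cd4`` defaults to 0 (QC disabled) because synthetic samples
    are usually far smaller than an acquisition stopping gate.
    """
    return PregateConfig(
        viability_threshold=spec.intensity["Viability"].midpoint,
        cd3_threshold=spec.intensity["CD3"].midpoint,
        scatter_min=-np.inf,
        scatter_max=np.inf,
        max_doublet_ratio=1.5,
        cd4_threshold=spec.intensity["CD4"].midpoint,
        min_live_cd4=min_live_cd4,
    )


def replication_spec(
    spec: CohortSpec,
    n_donors: int = 6,
    seed: int | None = None,
    drop_effects: Sequence[str] = (),
) -> CohortSpec:
    """An independent validation cohort: new donors, optionally with some
    platform effects absent (ratio 1)."""
    effects = {
        k: (1.0 if k in drop_effects else v)
        for k, v in spec.platform_effects.items()
    }
    return dataclasses.replace(
        spec,
        n_donors=n_donors,
        platform_effects=effects,
        donor_prefix="V",
        seed=spec.seed + 104729 if seed is None else seed,
    )


def write_cohort(
    samples: Sequence[EventMatrix],
    metadata: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
    provenance: str | None = None,
) -> None:
    """Write FCS files, the sidecar metadata CSV, and the truth JSON."""
    from .io import write_fcs, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for em in samples:
        write_fcs(em, outdir / f"{em.sample_id}.fcs")
    write_metadata(metadata, outdir / "metadata.csv", provenance=provenance)
    truth.to_json(outdir / "truth.json")
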