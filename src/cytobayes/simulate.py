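"""Synthetic assay-panel simulator.

Generates compound universes with the statistical structure the
modelling stack assumes: SAR series (groups of molecules sharing a
scaffold feature set plus random decoration features), a handful of
latent toxicity mechanisms each carried by some series, per-molecule
latent potency, and assays that observe a footprint of series through a
noisy percent-inhibition readout (baseline mean 1.2%, SD 9.8% — the
empirical noise profile of a large single-concentration cytotoxicity
HTS). IC50 follow-up assays re-measure the top primary hits plus some
filler compounds, giving the active-enriched confirmation sets the
cutoff-scan procedure needs. Everything is deterministic under a fixed
seed; simulated molecules use the same containers and table formats as
real, featurized ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import AssayDataset, LabelledSet, MoleculeRecord, build_store
from .label import label_top_fraction

PI_CLIP = (-20.0, 100.0)


@dataclass(frozen=True)
class AssaySpec:
    """One simulated assay: which series it screens, which mechanisms its
    endpoint responds to, and its noise profile (percent-inhibition %)."""

    assay_id: str
    footprint: tuple[int, ...]
    sensitivity: frozenset[int]
    noise_sd: float = 9.8
    baseline: float = 1.2

    def __post_init__(self) -> None:
        if not self.footprint:
            raise ValueError("assay footprint must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatorConfig:
    seed: int = 0
    n_series: int = 40
    series_size: int = 40
    n_mechanisms: int = 3
    p_toxic_series: float = 0.25
    #: explicit toxic series override (None = Bernoulli(p_toxic_series))
    toxic_series: tuple[int, ...] | None = None
    scaffold_features_per_series: int = 30
    decoration_features_per_molecule: int = 40
    #: decorations are drawn from a shared pool of "common fragment"
    #: features: real circular-fingerprint vocabularies are heavy-tailed,
    #: with frequent substituent features recurring across unrelated series
    decoration_pool_size: int = 2000
    feature_space_size: int = 2 ** 20
    #: latent potency range for toxic-series molecules (fraction of full
    #: effect); the weak end sits inside assay noise, as real series do
    potency_range: tuple[float, float] = (0.1, 0.9)
    #: toxic series get a higher mean logP (lipophilicity-toxicity correlation)
    lipophilicity_correlation: bool = True


@dataclass(frozen=True)
class MoleculeTruth:
    series: int
    mechanism: int | None  # None for non-toxic series
    potency: float         # 0 for non-toxic series


@dataclass
class Universe:
    config: SimulatorConfig
    records: list[MoleculeRecord]
    truth: dict[str, MoleculeTruth]
    series_members: dict[int, list[str]]
    toxic_series: set[int]
    store: dict[str, MoleculeRecord] = field(init=False)

    def __post_init__(self) -> None:
        self.store = build_store(self.records)


def _assay_rng(config_seed: int, assay_id: str) -> np.random.Generator:
    # stable per-assay stream: same universe seed + assay id -> same values
    return np.random.default_rng([config_seed, zlib.crc32(assay_id.encode())])


def generate_universe(config: SimulatorConfig | None = None) -> Universe:
    """Build the compound universe: series scaffolds, decorations, latent truth.

    Scaffold features are drawn without replacement across all series, so
    between-series scaffold collisions cannot occur; decoration features
    are drawn freely from the 2^20 identifier space (collisions are
    vanishingly rare and harmless).
    """
    config = config or SimulatorConfig()
    rng = np.random.default_rng(config.seed)
    n_scaffold_total = config.n_series * config.scaffold_features_per_series
    n_ids = n_scaffold_total + config.decoration_pool_size
    if n_ids > config.feature_space_size:
        raise ValueError("feature space too small for scaffolds + decoration pool")
    # one no-replacement draw: scaffold features can never collide with
    # each other or with the decoration pool
    ids = rng.choice(config.feature_space_size, size=n_ids, replace=False)
    scaffolds = ids[:n_scaffold_total].reshape(config.n_series, -1)
    deco_pool = ids[n_scaffold_total:]

    if config.toxic_series is not None:
        toxic = set(config.toxic_series)
        if not toxic <= set(range(config.n_series)):
            raise ValueError("toxic_series indices out of range")
    else:
        toxic = {s for s in range(config.n_series)
                 if rng.random() < config.p_toxic_series}
    mechanism = {s: int(rng.integers(config.n_mechanisms)) for s in sorted(toxic)}

    records: list[MoleculeRecord] = []
    truth: dict[str, MoleculeTruth] = {}
    series_members: dict[int, list[str]] = {s: [] for s in range(config.n_series)}
    lo, hi = config.potency_range
    for s in range(config.n_series):
        is_toxic = s in toxic
        logp_mean = 2.2 + (1.2 if is_toxic and config.lipophilicity_correlation else 0.0)
        for m in range(config.series_size):
            cid = f"s{s:03d}m{m:03d}"
            deco = deco_pool[rng.integers(0, len(deco_pool),
                                          size=config.decoration_features_per_molecule)]
            feats = frozenset(int(f) for f in scaffolds[s]) | frozenset(int(d) for d in deco)
            potency = float(rng.uniform(lo, hi)) if is_toxic else 0.0
            desc = {
                "AlogP": float(rng.normal(logp_mean, 0.9)),
                "MW": float(rng.normal(350.0, 60.0)),
                "HBD": float(rng.poisson(1.5)),
                "HBA": float(rng.poisson(4.0)),
                "RotB": float(rng.poisson(5.0)),
                "fPSA": float(rng.uniform(0.05, 0.45)),
            }
            records.append(MoleculeRecord(id=cid, features=feats, descriptors=desc))
            truth[cid] = MoleculeTruth(
                series=s, mechanism=mechanism.get(s), potency=potency)
            series_members[s].append(cid)
    return Universe(config=config, records=records, truth=truth,
                    series_members=series_members, toxic_series=toxic)


def generate_assay(universe: Universe, spec: AssaySpec) -> AssayDataset:
    """Screen the footprint series through a noisy percent-inhibition readout.

    value = baseline + 100·potency·[mechanism ∈ sensitivity] + N(0, noise_sd),
    clipped to [−20, 100]. A mechanism-insensitive assay sees pure noise.
    """
    rng = _assay_rng(universe.config.seed, spec.assay_id)
    measurements: dict[str, float] = {}
    for s in spec.footprint:
        for cid in universe.series_members[s]:
            t = universe.truth[cid]
            effect = 100.0 * t.potency if t.mechanism in spec.sensitivity else 0.0
            v = spec.baseline + effect + rng.normal(0.0, spec.noise_sd)
            measurements[cid] = float(np.clip(v, *PI_CLIP))
    return AssayDataset(
        assay_id=spec.assay_id, readout="percent_inhibition",
        measurements=measurements,
        metadata={"simulated": True, "footprint": list(spec.footprint)},
    )


def generate_ic50_assay(
    universe: Universe,
    spec: AssaySpec,
    intercept: float = 4.2,
    slope: float = 3.0,
    noise_sd: float = 0.2,
) -> AssayDataset:
    """A standalone dose-response screen reporting pIC50 over its footprint.

    pIC50 = intercept + slope·potency·[mechanism ∈ sensitivity] + N(0, noise_sd);
    compounds inert in this assay sit near the intercept (well below the
    conventional 5.5 toxicity call). This models IC50-readout panels that
    are screened independently of any percent-inhibition campaign.
    """
    rng = _assay_rng(universe.config.seed, spec.assay_id + ":pic50")
    measurements: dict[str, float] = {}
    for s in spec.footprint:
        for cid in universe.series_members[s]:
            t = universe.truth[cid]
            eff = t.potency if t.mechanism in spec.sensitivity else 0.0
            measurements[cid] = float(intercept + slope * eff + rng.normal(0.0, noise_sd))
    return AssayDataset(
        assay_id=spec.assay_id, readout="pIC50", measurements=measurements,
        metadata={"simulated": True, "footprint": list(spec.footprint)},
    )


@dataclass
class FollowupReport:
    dataset: AssayDataset
    parent_latent_toxic_rate: float
    followup_latent_toxic_rate: float

    @property
    def enrichment(self) -> float:
        if self.parent_latent_toxic_rate == 0:
            return float("inf")
        return self.followup_latent_toxic_rate / self.parent_latent_toxic_rate


def generate_ic50_followup(
    assay: AssayDataset,
    universe: Universe,
    top_n: int = 120,
    filler_n: int = 40,
    intercept: float = 4.2,
    slope: float = 3.0,
    potency_noise: float = 0.2,
) -> FollowupReport:
    """Confirmation assay: the top primary hits plus some filler compounds.

    pIC50 = intercept + slope·potency + N(0, potency_noise); with the
    defaults a non-toxic compound sits near 4.2 and a potent one above
    6, so the conventional pIC50 > 5.5 call separates them. The report
    carries the latent-toxic rate of the selection vs the parent screen
    (follow-up sets are strongly hit-enriched, as in real campaigns).
    """
    rng = _assay_rng(universe.config.seed, assay.assay_id + ":ic50")
    ranked = sorted(assay.measurements.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n > len(ranked):
        import warnings
        warnings.warn(f"top_n={top_n} exceeds assay size {len(ranked)}; truncated")
        top_n = len(ranked)
    chosen = [cid for cid, _ in ranked[:top_n]]
    rest = [cid for cid, _ in ranked[top_n:]]
    if filler_n and rest:
        filler_idx = rng.choice(len(rest), size=min(filler_n, len(rest)), replace=False)
        chosen += [rest[i] for i in sorted(filler_idx)]
    values = {
        cid: float(intercept + slope * universe.truth[cid].potency
                   + rng.normal(0.0, potency_noise))
        for cid in chosen
    }
    ds = AssayDataset(
        assay_id=assay.assay_id + "_ic50", readout="pIC50", measurements=values,
        metadata={"simulated": True, "parent": assay.assay_id},
    )

    def latent_rate(ids: Sequence[str]) -> float:
        return sum(universe.truth[c].potency > 0 for c in ids) / len(ids)

    return FollowupReport(
        dataset=ds,
        parent_latent_toxic_rate=latent_rate(list(assay.measurements)),
        followup_latent_toxic_rate=latent_rate(chosen),
    )


# ---------------------------------------------------------------------------
# packaged scenarios


@dataclass
class ScenarioPanel:
    universe: Universe
    assays: dict[str, AssayDataset]
    labels: dict[str, LabelledSet]

    @property
    def panel(self) -> list[tuple[AssayDataset, LabelledSet]]:
        return [(ds, self.labels[aid]) for aid, ds in self.assays.items()]


def scenario_chain(seed: int = 0, label_fraction: float = 0.20) -> ScenarioPanel:
    """Three assays with chained chemical-space footprints: A screens
    series 0–9, B series 5–14, C series 10–19. A∩B and B∩C overlap, A∩C
    is empty, so cross-prediction should connect A–B and B–C but not
    A–C: mutual predictivity is not transitive. Toxic series are planted
    at every third index so each overlap region contains shared SAR. The
    lipophilicity-toxicity descriptor correlation is off here: the
    scenario isolates transfer through shared chemistry, and a global
    property correlate would carry predictivity across any footprint gap.
    """
    config = SimulatorConfig(
        seed=seed, n_series=20, series_size=40, n_mechanisms=2,
        toxic_series=tuple(range(0, 20, 3)),
        lipophilicity_correlation=False,
    )
    universe = generate_universe(config)
    sens = frozenset(range(config.n_mechanisms))
    specs = [
        AssaySpec("A", tuple(range(0, 10)), sens),
        AssaySpec("B", tuple(range(5, 15)), sens),
        AssaySpec("C", tuple(range(10, 20)), sens),
    ]
    assays = {sp.assay_id: generate_assay(universe, sp) for sp in specs}
    labels = {aid: label_top_fraction(ds, label_fraction) for aid, ds in assays.items()}
    return ScenarioPanel(universe=universe, assays=assays, labels=labels)


def default_assay(universe: Universe, assay_id: str = "HTS1") -> AssayDataset:
    """One percent-inhibition screen over the whole universe, sensitive to
    every mechanism — the simplest learnable planted-signal dataset."""
    spec = AssaySpec(
        assay_id, tuple(range(universe.config.n_series)),
        frozenset(range(universe.config.n_mechanisms)),
    )
    return generate_assay(universe, spec)


@dataclass
class FollowupScenario:
    universe: Universe
    primary: AssayDataset
    followup: FollowupReport
    confirmed_actives: set[str]


def default_followup_scenario(
    seed: int = 0, pic50_cutoff: float = 5.5
) -> FollowupScenario:
    """Primary HTS over the default universe plus its IC50 confirmation
    assay; confirmed actives are the follow-up compounds with
    pIC50 > cutoff. This is the input the cutoff-scan procedure expects."""
    universe = generate_universe(SimulatorConfig(seed=seed))
    primary = default_assay(universe)
    followup = generate_ic50_followup(primary, universe)
    confirmed = {cid for cid, v in followup.dataset.measurements.items()
                 if v > pic50_cutoff}
    return FollowupScenario(universe=universe, primary=primary,
                            followup=followup, confirmed_actives=confirmed)


@dataclass
class PanelScenario:
    universe: Universe
    panel_pi: list[tuple[AssayDataset, LabelledSet]]
    panel_ic50: list[tuple[AssayDataset, LabelledSet]]


def default_panels(seed: int = 0, label_fraction: float = 0.20,
                   pic50_cutoff: float = 5.5) -> PanelScenario:
    """A percent-inhibition panel of three overlapping screens and an
    independent IC50-readout panel of three screens over a partially
    complementary region of the universe — the inputs of the merged-model
    procedure. PI assays are labelled by top fraction (equal hit rates
    across heterogeneous screens), IC50 assays by the fixed pIC50 cutoff."""
    from .label import label_fixed

    universe = generate_universe(SimulatorConfig(seed=seed))
    sens = frozenset(range(universe.config.n_mechanisms))
    pi_specs = [
        AssaySpec("P1", tuple(range(0, 20)), sens),
        AssaySpec("P2", tuple(range(5, 25)), sens),
        AssaySpec("P3", tuple(range(10, 30)), sens),
    ]
    ic_specs = [
        AssaySpec("Q1", tuple(range(15, 35)), sens),
        AssaySpec("Q2", tuple(range(20, 40)), sens),
        AssaySpec("Q3", tuple(range(25, 40)) + tuple(range(0, 5)), sens),
    ]
    panel_pi = []
    for sp in pi_specs:
        ds = generate_assay(universe, sp)
        panel_pi.append((ds, label_top_fraction(ds, label_fraction)))
    panel_ic50 = []
    for sp in ic_specs:
        ds = generate_ic50_assay(universe, sp)
        panel_ic50.append((ds, label_fixed(ds, pic50_cutoff)))
    return PanelScenario(universe=universe, panel_pi=panel_pi, panel_ic50=panel_ic50)
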