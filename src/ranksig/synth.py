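"""Synthetic data with recorded planted truths for every pipeline stage.

The generator emulates the data products of a two-cell-line perturbation
microarray study and its external references:

* a probe × sample experiment — two cell lines ("core", "margin"), vehicle
  and treated arms in quadruplicate, additive Gaussian noise on the log2
  scale, planted differential genes shifted in the treated arms of both
  lines;
* a multi-series background compendium against which rank profiles are
  taken, including constitutively high/low probes;
* a cancer-panel set of rank profiles in which exactly one entity is a
  noisy twin of the core profile;
* a drug-like signature bank with planted signatures at a stated
  concordance fraction with a reference signature, among size-matched
  decoys;
* a co-expression compendium in which each planted TF's module genes share
  a sparse latent perturbation factor with the TF.

Every planted entity is recorded in a :class:`TruthRecord` so downstream
recovery is checkable, and all randomness flows from a single integer seed
through named, deterministically-derived substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .connectivity import SignatureBank
from .differential import SignedGeneSignature
from .enrichment import GeneSetCollection
from .errors import ConfigError
from .matrix import ExpressionMatrix, ProbeGeneMap
from .ranks import RankProfile

__all__ = [
    "SimConfig",
    "TruthRecord",
    "default_config",
    "generate_experiment",
    "generate_background_compendium",
    "generate_panel",
    "generate_signature_bank",
    "generate_coexpression_compendium",
    "build_gene_set_collection",
]

CELL_LINES = ("core", "margin")
ARMS = ("vehicle", "treated")

# fixed substream labels: every generator stage draws from its own child
# of the config seed, so adding a stage never perturbs another's stream
_STAGES = {
    "universe": 0,
    "experiment": 1,
    "background": 2,
    "panel": 3,
    "bank": 4,
    "coexpr": 5,
    "sets": 6,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    ``probes_per_gene`` is a probability distribution over per-gene probe
    counts; by default 30% of genes carry 2–3 probes, exercising the
    probe-collapse rules.  ``n_probes`` is an optional total probe budget:
    probes beyond the mapped total are left unannotated; a budget below the
    mapped total is a configuration error.
    """

    n_genes: int = 2000
    n_probes: int | None = None
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.15, 3: 0.15}
    )
    n_background_series: int = 5
    samples_per_series: int = 10
    replicates_per_arm: int = 4
    noise_sd: float = 0.25
    planted_de: list[tuple[str, float]] = field(default_factory=list)
    planted_sets: list[tuple[str, list[str], str]] = field(default_factory=list)
    planted_drugs: list[tuple[str, float]] = field(default_factory=list)
    planted_tf_modules: list[tuple] = field(default_factory=list)  # (tf, module[, antimodule])
    panel_entities: int = 17
    panel_noise: float = 0.05
    bank_size: int = 100
    n_decoy_sets: int = 30
    coexpr_series: int = 10
    coexpr_samples_per_series: int = 30
    coexpr_perturb_frac: float = 0.08
    coexpr_amplitude: float = 4.0
    coexpr_loading: float = 1.0
    coexpr_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_background_series", "samples_per_series",
                     "replicates_per_arm", "panel_entities", "bank_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_probes is not None and self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        if not self.probes_per_gene:
            raise ConfigError("probes_per_gene distribution is empty")
        if min(self.probes_per_gene) < 1:
            raise ConfigError("per-gene probe counts must be >= 1")
        total = sum(self.probes_per_gene.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("probes_per_gene probabilities must sum to 1")
        for _, frac in self.planted_drugs:
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("drug concordance fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        universe = set(self.gene_names())
        planted = [g for g, _ in self.planted_de]
        planted += [g for _, members, _ in self.planted_sets for g in members]
        for entry in self.planted_tf_modules:
            if len(entry) not in (2, 3):
                raise ConfigError(
                    "planted_tf_modules entries are (tf, module) or (tf, module, antimodule)"
                )
            planted.append(entry[0])
            for members in entry[1:]:
                planted += list(members)
        missing = sorted(set(planted) - universe)
        if missing:
            raise ConfigError(f"planted genes outside the universe: {missing[:5]}")

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthRecord:
    """Planted ground truth of one synthetic study; JSON round-trippable."""

    de: list[tuple[str, float]] = field(default_factory=list)
    sets: list[tuple[str, list[str], str]] = field(default_factory=list)
    drugs: list[tuple[str, float]] = field(default_factory=list)
    tf_modules: list[tuple[str, list[str]]] = field(default_factory=list)
    panel_twin: str | None = None

    def de_genes(self, direction: str | None = None) -> set[str]:
        if direction == "up":
            return {g for g, e in self.de if e > 0}
        if direction == "down":
            return {g for g, e in self.de if e < 0}
        return {g for g, _ in self.de}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            de=[(g, float(e)) for g, e in d.get("de", [])],
            sets=[(n, list(m), s) for n, m, s in d.get("sets", [])],
            drugs=[(n, float(c)) for n, c in d.get("drugs", [])],
            tf_modules=[(t, list(m)) for t, m in d.get("tf_modules", [])],
            panel_twin=d.get("panel_twin"),
        )


def default_config(seed: int = 0) -> SimConfig:
    """The bundled demo study: planted DE, sets, drugs and TF modules.

    60 genes are shifted ±2 log2 units; the planted up and down gene sets
    are drawn from them; two planted drugs share the reference signature at
    concordance 0.9 and 0.1; three TFs get 30-gene co-expression modules —
    one module is the planted up genes (its TF should be recovered as
    positively correlated with the response), one the planted down genes,
    and one is independent of the response.
    """
    genes = [f"G{i:05d}" for i in range(1, 2001)]
    up = genes[10:40]
    down = genes[50:80]
    tf_a, tf_b, tf_c = genes[100], genes[140], genes[180]
    return SimConfig(
        planted_de=[(g, 2.0) for g in up] + [(g, -2.0) for g in down],
        planted_sets=[
            ("PLANTED_UP", list(up), "up"),
            ("PLANTED_DOWN", list(down), "down"),
        ],
        planted_drugs=[("DRUG_MIMIC", 0.9), ("DRUG_REVERSER", 0.1)],
        planted_tf_modules=[
            (tf_a, list(up), list(down)),   # activation mimics the response
            (tf_b, list(down), list(up)),   # activation reverses it
            (tf_c, genes[181:211]),         # unrelated to the response
        ],
        seed=seed,
    )


@dataclass
class _Universe:
    genes: list[str]
    probes: list[str]
    pmap: ProbeGeneMap
    const_high: list[str]
    const_low: list[str]
    base_level: np.ndarray  # shared per-probe mean tendency, log2 scale


def _universe(config: SimConfig) -> _Universe:
    rng = _stage_rng(config.seed, "universe")
    genes = config.gene_names()
    counts = sorted(config.probes_per_gene)
    probs = [config.probes_per_gene[c] for c in counts]
    per_gene = rng.choice(counts, size=len(genes), p=probs)
    mapping: dict[str, str] = {}
    probes: list[str] = []
    idx = 1
    for gene, k in zip(genes, per_gene):
        for _ in range(int(k)):
            probe = f"P{idx:06d}"
            probes.append(probe)
            mapping[probe] = gene
            idx += 1
    n_mapped = len(probes)
    if config.n_probes is not None:
        if config.n_probes < n_mapped:
            raise ConfigError(
                f"n_probes={config.n_probes} below the {n_mapped} mapped probes"
            )
        while idx <= config.n_probes:
            probes.append(f"P{idx:06d}")
            idx += 1
    # broad unimodal baseline on the log2 scale; exact law is irrelevant
    # downstream because only ranks are used
    base = rng.normal(8.0, 2.0, size=len(probes))
    n_const = max(1, len(probes) // 50)
    order = rng.permutation(len(probes))
    const_high = [probes[i] for i in order[:n_const]]
    const_low = [probes[i] for i in order[n_const:2 * n_const]]
    pos = {p: i for i, p in enumerate(probes)}
    for p in const_high:
        base[pos[p]] = rng.normal(15.0, 0.2)
    for p in const_low:
        base[pos[p]] = rng.normal(1.0, 0.2)
    return _Universe(genes, probes, ProbeGeneMap(mapping), const_high, const_low, base)


def generate_experiment(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ProbeGeneMap, TruthRecord]:
    """Two cell lines × {vehicle, treated} × replicates, with planted DE.

    Per-probe baselines are drawn independently per cell line around the
    shared probe tendency; treated arms shift every probe of a planted gene
    by its log2 effect (in both cell lines); i.i.d. Gaussian noise with
    ``noise_sd`` is added on the log2 scale.
    """
    uni = _universe(config)
    rng = _stage_rng(config.seed, "experiment")
    n_probes = len(uni.probes)
    effect = np.zeros(n_probes)
    gene_effect = dict(config.planted_de)
    for i, probe in enumerate(uni.probes):
        gene = uni.pmap.gene_of(probe)
        if gene in gene_effect:
            effect[i] = gene_effect[gene]

    columns: list[str] = []
    groups: dict[str, str] = {}
    data = []
    for line in CELL_LINES:
        line_base = uni.base_level + rng.normal(0.0, 1.0, size=n_probes)
        for arm in ARMS:
            shift = effect if arm == "treated" else 0.0
            for rep in range(1, config.replicates_per_arm + 1):
                sample = f"{line}_{arm}_{rep}"
                columns.append(sample)
                groups[sample] = f"{line}:{arm}"
                data.append(line_base + shift + rng.normal(0, config.noise_sd, n_probes))
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(uni.probes, name="probe"), columns=columns
    )
    truth = TruthRecord(
        de=list(config.planted_de),
        sets=[(n, list(m), d) for n, m, d in config.planted_sets],
        drugs=list(config.planted_drugs),
        tf_modules=[(e[0], list(e[1])) for e in config.planted_tf_modules],
    )
    return ExpressionMatrix(values, groups), uni.pmap, truth


def generate_background_compendium(config: SimConfig) -> list[ExpressionMatrix]:
    """Multi-series background over the same probe universe.

    Each series gets its own per-probe baseline shift; the constitutively
    high/low probes keep their extreme levels in every series, so their
    background mean ranks sit near 0 and 1 respectively.
    """
    if config.n_background_series < 2:
        raise ConfigError("need at least 2 background series")
    if config.samples_per_series < 2:
        raise ConfigError("need at least 2 samples per background series")
    uni = _universe(config)
    rng = _stage_rng(config.seed, "background")
    out = []
    for s in range(1, config.n_background_series + 1):
        series_base = uni.base_level + rng.normal(0.0, 1.0, size=len(uni.probes))
        cols = [f"bg{s}_{i}" for i in range(1, config.samples_per_series + 1)]
        vals = series_base[:, None] + rng.normal(
            0.0, 1.0, size=(len(uni.probes), len(cols))
        )
        out.append(
            ExpressionMatrix(
                pd.DataFrame(vals, index=pd.Index(uni.probes, name="probe"), columns=cols)
            )
        )
    return out


def generate_panel(
    config: SimConfig,
    grp_core: RankProfile,
    grp_margin: RankProfile,
    truth: TruthRecord | None = None,
) -> list[tuple[str, RankProfile]]:
    """Cancer-panel rank profiles with one noisy twin of the core profile.

    Exactly one entity is the core GRP plus bounded uniform rank noise
    (clipped to [−1, 1]); all others are independent random profiles over
    the same genes.  The twin's identity is recorded on ``truth`` when
    given.  The margin profile is accepted for interface symmetry but gets
    no twin: it represents the population that matches no panel entity.
    """
    if config.panel_entities < 2:
        raise ConfigError("panel needs at least 2 entities")
    del grp_margin  # no twin by design
    rng = _stage_rng(config.seed, "panel")
    genes = grp_core.values.index
    names = [f"PAN{i:02d}" for i in range(1, config.panel_entities + 1)]
    twin_idx = int(rng.integers(config.panel_entities))
    panel: list[tuple[str, RankProfile]] = []
    for i, name in enumerate(names):
        if i == twin_idx:
            noise = rng.uniform(-config.panel_noise, config.panel_noise, len(genes))
            vals = np.clip(grp_core.values.to_numpy() + noise, -1.0, 1.0)
        else:
            vals = rng.uniform(-1.0, 1.0, len(genes))
        panel.append((name, RankProfile(pd.Series(vals, index=genes), name=name)))
    if truth is not None:
        truth.panel_twin = names[twin_idx]
    return panel


def generate_signature_bank(
    config: SimConfig, reference: SignedGeneSignature
) -> SignatureBank:
    """Drug-like signature bank with planted concordant/discordant entries.

    Each planted drug covers the reference's genes, a stated fraction of
    them with the same sign and the rest flipped; decoys are size-matched
    random signatures over the gene universe.
    """
    if len(reference) == 0:
        raise ConfigError("reference signature is empty")
    rng = _stage_rng(config.seed, "bank")
    genes = np.array(config.gene_names())
    ref_genes = sorted(reference.genes())
    n_ref = len(ref_genes)

    signatures: dict[str, SignedGeneSignature] = {}
    for name, frac in config.planted_drugs:
        n_conc = int(round(frac * n_ref))
        order = rng.permutation(n_ref)
        concordant = {ref_genes[i] for i in order[:n_conc]}
        up, down = set(), set()
        for g in ref_genes:
            same = (g in concordant)
            ref_up = g in reference.up
            if (ref_up and same) or (not ref_up and not same):
                up.add(g)
            else:
                down.add(g)
        signatures[name] = SignedGeneSignature(
            frozenset(up), frozenset(down), {"planted_concordance": frac}
        )
    n_decoys = config.bank_size - len(signatures)
    if n_decoys < 0:
        raise ConfigError("bank_size smaller than the planted drug list")
    n_up, n_down = len(reference.up), len(reference.down)
    for i in range(1, n_decoys + 1):
        picked = rng.choice(genes, size=n_up + n_down, replace=False)
        signatures[f"DECOY{i:03d}"] = SignedGeneSignature(
            frozenset(picked[:n_up]), frozenset(picked[n_up:]), {"decoy": True}
        )
    return SignatureBank(signatures, universe=config.n_genes)


def generate_coexpression_compendium(config: SimConfig) -> list[ExpressionMatrix]:
    """Gene-level compendium in which planted TF modules co-vary.

    In every series a sparse latent perturbation drives each module: a
    fraction of samples carry a signed amplitude, and the TF and its module
    genes load on it (anti-module genes with the opposite sign) plus small
    private noise.  Non-module genes fluctuate independently with unit
    variance, so they reach the deviation threshold only at the nominal
    tail rate.
    """
    if not config.planted_tf_modules:
        raise ConfigError("planted_tf_modules is empty")
    rng = _stage_rng(config.seed, "coexpr")
    genes = config.gene_names()
    gene_pos = {g: i for i, g in enumerate(genes)}
    out = []
    for s in range(1, config.coexpr_series + 1):
        n_s = config.coexpr_samples_per_series
        cols = [f"cx{s}_{i}" for i in range(1, n_s + 1)]
        vals = 8.0 + rng.normal(0.0, 1.0, size=(len(genes), n_s))
        # genes in any module get small private noise; factor contributions
        # are additive, so genes shared between modules follow both factors
        involved: set[str] = set()
        for entry in config.planted_tf_modules:
            involved.add(entry[0])
            for members in entry[1:]:
                involved.update(members)
        for g in sorted(involved):
            vals[gene_pos[g], :] = 8.0 + rng.normal(0.0, config.coexpr_noise_sd, n_s)
        for entry in config.planted_tf_modules:
            tf, module = entry[0], entry[1]
            antimodule = entry[2] if len(entry) == 3 else []
            perturbed = rng.random(n_s) < config.coexpr_perturb_frac
            sign = rng.choice([-1.0, 1.0], size=n_s)
            factor = np.where(perturbed, sign * config.coexpr_amplitude, 0.0)
            for g, loading_sign in (
                [(tf, 1.0)]
                + [(g, 1.0) for g in module]
                + [(g, -1.0) for g in antimodule]
            ):
                vals[gene_pos[g], :] += loading_sign * config.coexpr_loading * factor
        out.append(
            ExpressionMatrix(
                pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=cols)
            )
        )
    return out


def build_gene_set_collection(config: SimConfig) -> GeneSetCollection:
    """Planted gene sets plus random decoy sets over the gene universe."""
    rng = _stage_rng(config.seed, "sets")
    genes = np.array(config.gene_names())
    collection = GeneSetCollection()
    for name, members, direction in config.planted_sets:
        collection.add(name, members, description=f"planted:{direction}")
    for i in range(1, config.n_decoy_sets + 1):
        size = int(rng.integers(10, 41))
        members = rng.choice(genes, size=size, replace=False)
        collection.add(f"DSET{i:03d}", members, description="decoy")
    return collection


def check_truth(truth: TruthRecord, config: SimConfig) -> None:
    """Post-generation consistency check: every planted entity must exist."""
    universe = set(config.gene_names())
    named = set(truth.de_genes())
    named |= {g for _, members, _ in truth.sets for g in members}
    named |= {tf for tf, _ in truth.tf_modules}
    named |= {g for _, members in truth.tf_modules for g in members}
    missing = sorted(named - universe)
    if missing:
        raise ConfigError(f"truth names absent entities: {missing[:5]}")
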