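"""Synthetic two-cohort small RNA-seq generator with planted ground truth.

Emulates the study design the pipeline targets: a discovery cohort with
fetal lung (FL), adult non-neoplastic lung (ANL) and lung adenocarcinoma
(LUAD) groups, and a validation cohort with ANL and LUAD only. Each planted
miRNA belongs to one class that fixes the groups in which it is "on":

====================  =========================
class                 expressed ("on") in
====================  =========================
oncofetal             FL and LUAD (not ANL)
fetal_only            FL
tumour_only           LUAD
under_in_both         ANL
ubiquitous            all groups
silent                no group
background            all groups (high level)
====================  =========================

Counts follow a negative-binomial model: for miRNA *i* with per-group mean
RPM ``μ_ig`` (expressed_mean_rpm scaled by a fixed per-miRNA lognormal
factor when "on", silent_mean_rpm when "off") and sample *j* with library
size ``L_j`` drawn uniformly from ``library_size_range``, the count is
``NB(mean = μ_ig · L_j / 1e6, dispersion = nb_dispersion)`` (variance
``m + m²/k``). The ``background`` class is abundant filler shared by every
group, sized so that the expected RPM total of each sample is 1e6; this
keeps the planted RPM scale intact after self-contained column-sum RPM
normalization, the way the bulk of a real miRNome dwarfs any deregulated
panel.

A configurable fraction of oncofetal loci is placed inside a designated
genomic cluster region (default the C14MC imprinted cluster band on chr14)
so that cluster-localization queries have ground truth. Survival times for
LUAD patients are exponential with hazard multiplied by ``hazard_ratio``
when the patient is RPM-positive for any designated miRNA, censored by an
independent exponential.

One global seed feeds independent substreams for counts, loci and survival,
so e.g. adding survival generation never perturbs the count draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_matrix import ExpressionMatrix, GenomicLocus, format_locus

GROUPS_DISCOVERY = ("FL", "ANL", "LUAD")
GROUPS_VALIDATION = ("ANL", "LUAD")

#: groups in which each planted class is "on"
CLASS_ON_GROUPS: dict[str, frozenset] = {
    "oncofetal": frozenset({"FL", "LUAD"}),
    "fetal_only": frozenset({"FL"}),
    "tumour_only": frozenset({"LUAD"}),
    "under_in_both": frozenset({"ANL"}),
    "ubiquitous": frozenset({"FL", "ANL", "LUAD"}),
    "silent": frozenset(),
    "background": frozenset({"FL", "ANL", "LUAD"}),
}

# substream ids for the per-purpose random generators
_STREAM_COUNTS, _STREAM_LOCI, _STREAM_SURVIVAL = 0, 1, 2


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults mirror the emulated study: discovery FL=25/ANL=77/LUAD=63,
    validation ANL=38/LUAD=389, a 13-member planted oncofetal class, and a
    cluster fraction of 5/13 inside the designated chr14 region.
    """

    discovery_sizes: dict = field(
        default_factory=lambda: {"FL": 25, "ANL": 77, "LUAD": 63}
    )
    validation_sizes: dict = field(
        default_factory=lambda: {"ANL": 38, "LUAD": 389}
    )
    class_counts: dict = field(
        default_factory=lambda: {
            "oncofetal": 13,
            "fetal_only": 20,
            "tumour_only": 20,
            "under_in_both": 15,
            "ubiquitous": 30,
            "silent": 20,
            "background": 50,
        }
    )
    nb_dispersion: float = 10.0
    tumour_positive_fraction: float = 0.5  # LUAD patients reactivating each hit
    expressed_mean_rpm: float = 50.0
    silent_mean_rpm: float = 0.05
    mean_scatter_sigma: float = 0.4  # lognormal sigma of per-miRNA mean factors
    library_size_range: tuple = (5_000_000, 20_000_000)
    cluster_region: GenomicLocus = GenomicLocus("chr14", "+", 100_800_000, 101_100_000)
    cluster_fraction: float = 5.0 / 13.0  # oncofetal loci planted inside the region
    baseline_hazard: float = 0.01
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name, sizes in (("discovery", self.discovery_sizes),
                            ("validation", self.validation_sizes)):
            for group, n in sizes.items():
                if n <= 0:
                    raise ConfigError(f"{name} group {group} has {n} samples")
        for cls, n in self.class_counts.items():
            if cls not in CLASS_ON_GROUPS:
                raise ConfigError(f"unknown miRNA class {cls!r}")
            if n < 0:
                raise ConfigError(f"negative count for class {cls!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.expressed_mean_rpm <= 0 or self.silent_mean_rpm < 0:
            raise ConfigError("mean RPM levels out of range")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be a positive (lo, hi) pair")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ConfigError("hazards must be positive")
        if self.censoring_rate < 0:
            raise ConfigError("censoring rate must be non-negative")
        if not 0 <= self.cluster_fraction <= 1:
            raise ConfigError("cluster_fraction must lie in [0, 1]")
        if not 0 < self.tumour_positive_fraction <= 1:
            raise ConfigError("tumour_positive_fraction must lie in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground-truth class labels and genomic loci of the simulated miRNAs."""

    classes: dict  # mirna_id -> class label
    loci: dict  # mirna_id -> GenomicLocus
    mean_factors: dict  # mirna_id -> per-miRNA lognormal mean factor

    def ids_of(self, *class_labels: str) -> list[str]:
        wanted = set(class_labels)
        return [m for m, c in self.classes.items() if c in wanted]

    @property
    def oncofetal_ids(self) -> list[str]:
        return self.ids_of("oncofetal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": pd.Series(self.classes),
                "locus": pd.Series({m: format_locus(l) for m, l in self.loci.items()}),
            }
        ).rename_axis("mirna_id")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _mirna_names(class_counts: dict) -> dict[str, str]:
    names = {}
    for cls in CLASS_ON_GROUPS:  # fixed iteration order for determinism
        for i in range(class_counts.get(cls, 0)):
            names[f"sim-mir-{cls}-{i + 1:03d}"] = cls
    return names


def _plant_loci(truth_classes: dict, cfg: SimConfig,
                rng: np.random.Generator) -> dict[str, GenomicLocus]:
    """Random mature-miRNA loci; a set fraction of oncofetal ones in-cluster."""
    region = cfg.cluster_region
    onco = [m for m, c in truth_classes.items() if c == "oncofetal"]
    n_in = int(round(cfg.cluster_fraction * len(onco)))
    in_cluster = set(onco[:n_in])
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    loci = {}
    for mirna in truth_classes:
        length = int(rng.integers(19, 26))  # mature miRNA length range
        if mirna in in_cluster:
            start = int(rng.integers(region.start, region.end - length))
            chrom = region.chrom
        else:
            # anywhere else; avoid the cluster region to keep truth unambiguous
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, 150_000_000))
            if chrom == region.chrom and region.start - length <= start <= region.end:
                start = region.end + 10_000 + start % 1_000_000
        strand = "+" if rng.random() < 0.5 else "-"
        loci[mirna] = GenomicLocus(chrom, strand, start, start + length - 1)
    return loci


def _simulate_cohort(cohort: str, sizes: dict, truth: PlantedTruth,
                     cfg: SimConfig, rng: np.random.Generator) -> ExpressionMatrix:
    mirnas = list(truth.classes)
    groups_per_sample: list[str] = []
    sample_ids: list[str] = []
    for group in (g for g in ("FL", "ANL", "LUAD") if g in sizes):
        for i in range(sizes[group]):
            sample_ids.append(f"{cohort[0].upper()}_{group}_{i + 1:03d}")
            groups_per_sample.append(group)

    lo, hi = cfg.library_size_range
    lib = rng.integers(int(lo), int(hi) + 1, size=len(sample_ids))

    # per-group expected RPM of every miRNA; background filler closes the
    # composition so each group's expected total is exactly 1e6
    group_mean_rpm: dict[str, np.ndarray] = {}
    bg = [i for i, m in enumerate(mirnas) if truth.classes[m] == "background"]
    for group in set(groups_per_sample):
        mu = np.empty(len(mirnas))
        for i, m in enumerate(mirnas):
            cls = truth.classes[m]
            if cls == "background":
                mu[i] = 0.0  # filled below
            elif group in CLASS_ON_GROUPS[cls]:
                mu[i] = cfg.expressed_mean_rpm * truth.mean_factors[m]
            else:
                mu[i] = cfg.silent_mean_rpm
        if bg:
            mu[bg] = max(1e6 - mu.sum(), 0.0) / len(bg)
        group_mean_rpm[group] = mu

    mean_rpm = np.column_stack([group_mean_rpm[g] for g in groups_per_sample])

    # Tumour heterogeneity: miRNAs reactivated in LUAD (oncofetal and
    # tumour-only classes) are expressed only in a Bernoulli fraction of
    # LUAD patients; the rest stay at the silent level. This is what makes
    # RPM≥1 positivity a non-trivial patient stratification.
    f_pos = cfg.tumour_positive_fraction
    if f_pos < 1.0:
        reactivated = np.array(
            [truth.classes[m] in ("oncofetal", "tumour_only") for m in mirnas]
        )
        luad_cols = np.array([g == "LUAD" for g in groups_per_sample])
        cells = np.outer(reactivated, luad_cols)
        off = cells & (rng.random(mean_rpm.shape) >= f_pos)
        mean_rpm = np.where(off, cfg.silent_mean_rpm, mean_rpm)

    mean_counts = mean_rpm * (lib[np.newaxis, :] / 1e6)
    k = cfg.nb_dispersion
    counts = np.zeros_like(mean_counts)
    pos = mean_counts > 0
    counts[pos] = rng.negative_binomial(k, k / (k + mean_counts[pos]))

    values = pd.DataFrame(counts, index=pd.Index(mirnas, name="mirna_id"),
                          columns=sample_ids)
    meta = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "group": groups_per_sample,
            "cohort": cohort,
            "total_reads": lib,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values=values, meta=meta, unit="counts")


def generate_cohorts(cfg: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Simulate the discovery and validation count matrices plus ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    matrices, loci and class labels.
    """
    cfg.validate()
    classes = _mirna_names(cfg.class_counts)
    rng_counts = _rng(cfg.seed, _STREAM_COUNTS)
    rng_loci = _rng(cfg.seed, _STREAM_LOCI)

    sigma = cfg.mean_scatter_sigma
    factors = {
        m: float(np.exp(rng_counts.normal(0.0, sigma))) if c != "background" else 1.0
        for m, c in classes.items()
    }
    truth = PlantedTruth(classes=classes, mean_factors=factors,
                         loci=_plant_loci(classes, cfg, rng_loci))
    discovery = _simulate_cohort("discovery", cfg.discovery_sizes, truth, cfg, rng_counts)
    validation = _simulate_cohort("validation", cfg.validation_sizes, truth, cfg, rng_counts)
    return discovery, validation, truth


def generate_survival(cfg: SimConfig, m: ExpressionMatrix,
                      positive_mirnas: list[str]) -> pd.DataFrame:
    """Exponential survival for LUAD patients, hazard tied to miRNA positivity.

    A patient is positive when any designated miRNA has RPM ≥ 1 in their
    sample; positives have hazard ``baseline_hazard × hazard_ratio``,
    negatives ``baseline_hazard``. Censoring is an independent exponential
    with rate ``censoring_rate`` (0 disables censoring). Returns a DataFrame
    indexed by sample id with columns time, event, stratum.
    """
    cfg.validate()
    missing = [x for x in positive_mirnas if x not in m.values.index]
    if missing:
        raise ConfigError(f"designated miRNAs absent from matrix: {missing}")
    luad = m.samples_in_group("LUAD")
    if not luad:
        raise ConfigError("no LUAD samples to simulate survival for")

    if m.unit == "rpm":
        rpm = m.values
    else:
        from .io_matrix import normalize_rpm

        rpm = normalize_rpm(m).values
    positive = (rpm.loc[positive_mirnas, luad] >= 1.0).any(axis=0).to_numpy()

    rng = _rng(cfg.seed, _STREAM_SURVIVAL)
    hazard = cfg.baseline_hazard * np.where(positive, cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / cfg.censoring_rate, size=len(luad))
    else:
        censor_time = np.full(len(luad), np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return pd.DataFrame(
        {
            "time": time,
            "event": event.astype(int),
            "stratum": np.where(positive, "positive", "negative"),
        },
        index=pd.Index(luad, name="sample_id"),
    )
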