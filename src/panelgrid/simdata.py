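"""Synthetic probe-level and probe-set-level case-control expression data.

The generator emulates a balanced two-group microarray study (24 rejection
cases vs 24 non-rejecting controls on a ~54k probe-set array, scalable down)
with a planted fraction of differentially expressed probe-sets, probe-set
blocks of individual probes whose across-array consistency varies, a
feature-to-gene annotation table, and GMT gene-set collections some of which
are deliberately loaded with differential genes.

Probe-level model, on the log2 scale::

    intensity(p, j) = baseline(s) + affinity(p) + effect(s) * case(j)
                      + shared_signal(s, j) + eps(p, j)

where ``s`` is the probe-set owning probe ``p`` and ``j`` indexes arrays.
"Inconsistent" probe-sets replace the shared per-array signal with
independent per-probe noise of the same magnitude, so their probe profiles
disagree across arrays and probe-consistency pre-filters can reject them.

The probe-set-level matrix (used when probe-level processing is skipped) is
the summarization-free truth ``baseline + effect * case + shared_signal +
eps``.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` child streams, so adding a stream never
perturbs earlier ones and identical (seed, config) pairs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE_LABEL = "AR"
CONTROL_LABEL = "NR"

# stable per-stream identifiers appended to the master SeedSequence
_STREAMS = {
    "labels": 0,
    "baseline": 1,
    "effects": 2,
    "signal": 3,
    "noise": 4,
    "affinity": 5,
    "inconsistent": 6,
    "gene_sets": 7,
    "annotation": 8,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: 24 cases + 24
    controls, a planted 5% of differential probe-sets with |log2 FC| in
    [0.5, 1.5] split evenly up/down, log2 baselines near 7-10 and 11 probes
    per probe-set.
    """

    n_case: int = 24
    n_control: int = 24
    n_probesets: int = 2_000
    probes_per_set: int = 11
    de_fraction: float = 0.05
    effect_low: float = 0.5
    effect_high: float = 1.5
    frac_up: float = 0.5
    baseline_mean: float = 7.5
    baseline_sd: float = 1.5
    signal_sd: float = 1.25
    noise_sd: float = 0.7
    frac_inconsistent: float = 0.3
    probe_affinity_sd: float = 0.5
    n_gene_sets: int = 50
    n_enriched_sets: int = 5
    gene_set_size_range: tuple[int, int] = (10, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both classes need at least one sample")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_low > self.effect_high:
            raise ValueError("effect_low must not exceed effect_high")
        if self.effect_low < 0:
            raise ValueError("effect bounds are magnitudes; must be >= 0")
        for name in ("baseline_sd", "signal_sd", "noise_sd", "probe_affinity_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_inconsistent <= 1.0:
            raise ValueError("frac_inconsistent must lie in [0, 1]")
        if not 0.0 <= self.frac_up <= 1.0:
            raise ValueError("frac_up must lie in [0, 1]")
        if 0 < self.de_fraction and round(self.de_fraction * self.n_probesets) < 1:
            raise ValueError(
                "de_fraction * n_probesets < 1: no effect can be planted"
            )
        lo, hi = self.gene_set_size_range
        if lo < 1 or lo > hi:
            raise ValueError("invalid gene_set_size_range")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    de_feature_ids: list[str]
    de_effects: dict[str, float]
    inconsistent_set_ids: list[str]
    enriched_set_ids: list[str] = field(default_factory=list)


@dataclass
class ProbeLevelSet:
    """One probe-set block: probes x arrays log2 intensities."""

    probeset_id: str
    probe_ids: list[str]
    arrays: list[str]
    values: np.ndarray  # (n_probes, n_arrays)


@dataclass
class ProbeLevelCollection:
    blocks: list[ProbeLevelSet]

    @property
    def arrays(self) -> list[str]:
        return self.blocks[0].arrays if self.blocks else []

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class ExpressionMatrix:
    """Features x samples log2 expression with binary class labels."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    labels: pd.Series  # sample id -> CASE_LABEL / CONTROL_LABEL

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels.loc[self.values.columns] == CASE_LABEL).to_numpy()

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.labels)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.labels.loc[ids])


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(config.seed), _STREAMS[stream]])
    return np.random.Generator(np.random.PCG64(ss))


def _feature_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"PS{idx:0{width}d}_at" for idx in range(1, n + 1)]


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Feature -> gene symbol/title table.

    About 10% of genes own two probe-sets (mirrors real arrays, where a gene
    may be interrogated by several probe-sets), assigned from a seeded
    stream.
    """
    config.validate()
    features = _feature_ids(config.n_probesets)
    n_genes = max(1, int(np.ceil(config.n_probesets * 0.9)))
    width = max(5, len(str(n_genes)))
    genes = [f"GENE{idx:0{width}d}" for idx in range(1, n_genes + 1)]
    rng = _rng(config, "annotation")
    # every gene used at least once, surplus probe-sets doubled up at random
    assigned = list(range(n_genes))
    extra = rng.integers(0, n_genes, size=config.n_probesets - n_genes)
    assigned = (assigned + list(extra))[: config.n_probesets]
    rng.shuffle(assigned)
    return pd.DataFrame(
        {
            "feature_id": features,
            "gene_symbol": [genes[i] for i in assigned],
            "gene_title": [f"synthetic gene {genes[i][4:]}" for i in assigned],
        }
    ).set_index("feature_id")


def simulate_cohort(
    config: SimConfig, probe_level: bool = True
) -> tuple[ProbeLevelCollection | None, ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Generate the full synthetic cohort.

    Returns (probe_level_collection, probeset_matrix, ground_truth,
    annotation).  With ``probe_level=False`` the probe block generation is
    skipped (first element ``None``); the probe-set matrix and ground truth
    are unchanged, which keeps feature-level experiments on large arrays
    cheap.
    """
    config.validate()
    n = config.n_case + config.n_control
    n_feat = config.n_probesets
    features = _feature_ids(n_feat)
    samples = [f"S{j:03d}" for j in range(1, n + 1)]

    # class labels: interleave then shuffle for arbitrary column order
    lab_rng = _rng(config, "labels")
    labels_arr = np.array(
        [CASE_LABEL] * config.n_case + [CONTROL_LABEL] * config.n_control
    )
    lab_rng.shuffle(labels_arr)
    labels = pd.Series(labels_arr, index=samples, name="class")
    case = (labels_arr == CASE_LABEL).astype(float)

    base_rng = _rng(config, "baseline")
    baseline = base_rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)

    # planted differential effects: signed log2 shifts applied to cases
    eff_rng = _rng(config, "effects")
    n_de = int(round(config.de_fraction * n_feat))
    de_idx = np.sort(eff_rng.choice(n_feat, size=n_de, replace=False))
    magnitudes = eff_rng.uniform(config.effect_low, config.effect_high, size=n_de)
    n_up = int(round(config.frac_up * n_de))
    signs = np.ones(n_de)
    signs[n_up:] = -1.0
    eff_rng.shuffle(signs)
    effects = np.zeros(n_feat)
    effects[de_idx] = magnitudes * signs

    sig_rng = _rng(config, "signal")
    shared = sig_rng.normal(0.0, config.signal_sd, size=(n_feat, n))

    inc_rng = _rng(config, "inconsistent")
    n_inc = int(round(config.frac_inconsistent * n_feat))
    inc_idx = np.sort(inc_rng.choice(n_feat, size=n_inc, replace=False))
    inconsistent = np.zeros(n_feat, dtype=bool)
    inconsistent[inc_idx] = True

    # probe-set-level residual noise: the noise a summary over
    # probes_per_set probes would retain, so the feature matrix matches
    # what probe-level summarization of the same design produces
    noise_rng = _rng(config, "noise")
    ps_noise_sd = config.noise_sd / np.sqrt(config.probes_per_set)
    ps_noise = noise_rng.normal(0.0, ps_noise_sd, size=(n_feat, n))
    ps_values = baseline[:, None] + effects[:, None] * case[None, :] + shared + ps_noise
    expr = ExpressionMatrix(
        pd.DataFrame(ps_values, index=features, columns=samples), labels
    )

    collection = None
    if probe_level:
        aff_rng = _rng(config, "affinity")
        p = config.probes_per_set
        affinity = aff_rng.normal(0.0, config.probe_affinity_sd, size=(n_feat, p))
        probe_noise = noise_rng.normal(0.0, config.noise_sd, size=(n_feat, p, n))
        # inconsistent sets: shared per-array signal replaced with
        # independent per-probe wander of the same magnitude
        wander = noise_rng.normal(0.0, config.signal_sd, size=(n_feat, p, n))
        blocks = []
        for i, fid in enumerate(features):
            common = baseline[i] + effects[i] * case  # (n,)
            if inconsistent[i]:
                sig = wander[i]
            else:
                sig = np.broadcast_to(shared[i], (p, n))
            vals = common[None, :] + affinity[i][:, None] + sig + probe_noise[i]
            blocks.append(
                ProbeLevelSet(
                    probeset_id=fid,
                    probe_ids=[f"{fid}:p{q + 1:02d}" for q in range(p)],
                    arrays=samples,
                    values=np.ascontiguousarray(vals),
                )
            )
        collection = ProbeLevelCollection(blocks)

    truth = GroundTruth(
        de_feature_ids=[features[i] for i in de_idx],
        de_effects={features[i]: float(effects[i]) for i in de_idx},
        inconsistent_set_ids=[features[i] for i in inc_idx],
    )
    annotation = simulate_annotation(config)
    return collection, expr, truth, annotation


def simulate_gene_sets(
    truth: GroundTruth, annotation: pd.DataFrame, config: SimConfig
) -> tuple[dict[str, list[str]], GroundTruth]:
    """GMT-style gene sets; a chosen few are loaded with differential genes.

    Enriched sets draw at least half their members from genes owning a
    planted differential probe-set; the rest sample the gene universe
    uniformly.  Updates ``truth.enriched_set_ids`` in place and also returns
    the collection as an ordered dict name -> member genes.
    """
    config.validate()
    universe = sorted(set(annotation["gene_symbol"]) - {"---"})
    lo, hi = config.gene_set_size_range
    if hi > len(universe):
        raise ValueError("gene_set_size_range exceeds the gene universe")
    de_genes = sorted(
        set(annotation.loc[annotation.index.isin(truth.de_feature_ids), "gene_symbol"])
        - {"---"}
    )
    rng = _rng(config, "gene_sets")
    n_enriched = min(config.n_enriched_sets, config.n_gene_sets)
    if not de_genes:
        n_enriched = 0
    sets: dict[str, list[str]] = {}
    enriched_ids = []
    for s in range(config.n_gene_sets):
        name = f"SET_{s + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if s < n_enriched:
            n_from_de = min(len(de_genes), max(int(np.ceil(size / 2)), 1))
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            pool = [g for g in universe if g not in members]
            n_fill = min(size - n_from_de, len(pool))
            if n_fill > 0:
                members += list(rng.choice(pool, size=n_fill, replace=False))
            enriched_ids.append(name)
        else:
            members = list(rng.choice(universe, size=min(size, len(universe)),
                                      replace=False))
        sets[name] = sorted(members)
    truth.enriched_set_ids = enriched_ids
    return sets, truth


# ---------------------------------------------------------------------------
# text-format writers (TSV / GMT); readers live in panelgrid.io


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_labels(expr: ExpressionMatrix, path: str | Path) -> None:
    lab = expr.labels.rename_axis("sample_id").rename("class")
    lab.to_frame().to_csv(path, sep="\t")


def write_probe_level(collection: ProbeLevelCollection, path: str | Path) -> None:
    rows = []
    for block in collection:
        for q, pid in enumerate(block.probe_ids):
            rows.append((block.probeset_id, pid, *block.values[q]))
    cols = ["probeset_id", "probe_id", *collection.arrays]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t")


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, f"synthetic set {name}", *members]) + "\n")
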