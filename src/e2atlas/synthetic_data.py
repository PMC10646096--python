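"""Ground-truth generators for every input the analysis pipeline consumes.

The defaults mirror the study design the pipeline targets: multiplexed
16-plex TMT sets with 3 knockdown replicates per condition and 4 in-set
non-targeting controls, paired TPM matrices with partial mRNA/protein
concordance, bait/control IP-MS spectral counts (3 bait replicates, 10
controls) with Poisson contaminant background, and fluorescence fields of
nuclei plus functional/ghost peroxisome puncta.  Every generator is
deterministic for a fixed seed, and the noise-free limits are exactly
invertible by the corresponding analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_omics import AbundanceMatrix, ExpressionMatrix
from .interactome_scoring import CONTROL, SpectralCountTable
from .import_imaging import MultiChannelImage

#: Between-set (TMT batch) offset SD on the log2 scale, drawn once per
#: (batch, protein).  Creates the intra- vs extra-batch structure the
#: similarity z-scoring is designed to absorb.
DEFAULT_BATCH_SD = 0.5

#: Replicate-level measurement noise SD in log2 units, typical of deep
#: TMT quantification after normalisation.
DEFAULT_NOISE_SD = 0.3

PUNCTUM_CLASSES = ("functional", "ghost", "pts1_only")


# ---------------------------------------------------------------------------
# experiment designs and regulation truth
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Layout of a multi-set knockdown screen.

    conditions are E2 labels; ``batch_of`` assigns each to exactly one TMT
    set.  Each set carries ``reps_per_condition`` knockdown replicates per
    condition and ``controls_per_batch`` non-targeting control channels.
    """

    conditions: list[str]
    batch_of: dict[str, int]
    reps_per_condition: int = 3
    controls_per_batch: int = 4
    n_proteins: int = 1000

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("empty design")
        missing = set(self.conditions) - set(self.batch_of)
        if missing:
            raise ValueError(f"conditions without a batch: {sorted(missing)}")
        if self.reps_per_condition < 2 or self.controls_per_batch < 2:
            raise ValueError("need >=2 replicates and >=2 controls per batch")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >=1")

    @property
    def batches(self) -> list[int]:
        return sorted({self.batch_of[c] for c in self.conditions})

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def protein_ids(self) -> pd.Index:
        width = len(str(self.n_proteins))
        return pd.Index([f"P{i:0{width}d}" for i in range(1, self.n_proteins + 1)],
                        name="protein")

    def sample_meta(self) -> pd.DataFrame:
        """Sample table: per batch, condition replicates then controls."""
        rows = []
        for b in self.batches:
            for cond in [c for c in self.conditions if self.batch_of[c] == b]:
                for r in range(1, self.reps_per_condition + 1):
                    rows.append((f"B{b}_{cond}_r{r}", cond, b, r, False))
            for r in range(1, self.controls_per_batch + 1):
                rows.append((f"B{b}_NT_c{r}", "NT", b, r, True))
        meta = pd.DataFrame(rows, columns=["sample", "condition", "batch",
                                           "replicate", "is_control"])
        return meta.set_index("sample")


def default_design(n_proteins: int = 1000, n_batches: int = 6,
                   conditions_per_batch: int = 2) -> ExperimentDesign:
    """Convenience screen layout: E2-style labels spread over TMT sets."""
    conditions, batch_of = [], {}
    k = 0
    for b in range(1, n_batches + 1):
        for _ in range(conditions_per_batch):
            label = f"E2{chr(ord('a') + k % 26)}{'' if k < 26 else k // 26}"
            conditions.append(label)
            batch_of[label] = b
            k += 1
    return ExperimentDesign(conditions=conditions, batch_of=batch_of,
                            n_proteins=n_proteins)


@dataclass
class RegulationTruth:
    """True (condition, protein) -> log2 effect map plus mRNA concordance.

    ``mrna_concordance`` is the probability that a protein effect is
    mirrored by a matching fold-change of its gene.
    """

    effects: dict[tuple[str, str], float]
    mrna_concordance: float = 0.5

    def __post_init__(self) -> None:
        for key, eff in self.effects.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for {key}")
        if not 0.0 <= self.mrna_concordance <= 1.0:
            raise ValueError("mrna_concordance must lie in [0, 1]")

    def validate_against(self, design: ExperimentDesign) -> None:
        conds = {c for c, _ in self.effects}
        extra = conds - set(design.conditions)
        if extra:
            raise ValueError(f"conditions absent from design: {sorted(extra)}")
        proteins = set(design.protein_ids)
        extra_p = {p for _, p in self.effects} - proteins
        if extra_p:
            raise ValueError(f"proteins absent from design: {sorted(extra_p)[:5]}")

    def regulated_by(self, condition: str) -> dict[str, float]:
        return {p: e for (c, p), e in self.effects.items() if c == condition}


def random_truth(design: ExperimentDesign, n_regulated: int = 50,
                 effect_size: float = 1.0, mrna_concordance: float = 0.5,
                 seed: int = 0) -> RegulationTruth:
    """Independent random targets per condition, effects +-effect_size."""
    rng = np.random.default_rng(seed)
    proteins = design.protein_ids
    effects: dict[tuple[str, str], float] = {}
    for cond in design.conditions:
        targets = rng.choice(len(proteins), size=n_regulated, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_regulated)
        for idx, s in zip(targets, signs):
            effects[(cond, proteins[idx])] = s * effect_size
    return RegulationTruth(effects=effects, mrna_concordance=mrna_concordance)


def shared_target_truth(design: ExperimentDesign,
                        similar_pairs: list[tuple[str, str]],
                        n_regulated: int = 50, shared_fraction: float = 0.5,
                        effect_size: float = 1.0, mrna_concordance: float = 0.5,
                        seed: int = 0) -> RegulationTruth:
    """Truth with designated condition pairs drawing same-sign effects from
    a common target pool.

    Each pair in ``similar_pairs`` shares ``shared_fraction`` of its
    regulated proteins (same protein, same sign, same magnitude); remaining
    targets are private.  Conditions in no pair get fully private targets.
    This is the minimal mechanism producing graded pairwise R^2.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = list(design.protein_ids)
    rng.shuffle(proteins)
    n_shared = int(round(shared_fraction * n_regulated))
    n_reserved = n_shared * len(similar_pairs)
    if n_reserved + n_regulated > len(proteins):
        raise ValueError("n_proteins too small for the requested target sets")
    # reserved disjoint pools guarantee the designated sharing; private
    # targets are drawn from the remainder and may overlap across
    # conditions by chance, as in a real screen
    reserved, free = proteins[:n_reserved], proteins[n_reserved:]

    effects: dict[tuple[str, str], float] = {}
    paired = set()
    for i, (a, b) in enumerate(similar_pairs):
        for c in (a, b):
            if c not in design.conditions:
                raise ValueError(f"condition {c!r} absent from design")
            if c in paired:
                raise ValueError(f"condition {c!r} appears in several pairs")
            paired.add(c)
        shared = reserved[i * n_shared:(i + 1) * n_shared]
        signs = rng.choice([-1.0, 1.0], size=n_shared)
        for p, s in zip(shared, signs):
            effects[(a, p)] = s * effect_size
            effects[(b, p)] = s * effect_size
    for c in design.conditions:
        n_private = (n_regulated - n_shared) if c in paired else n_regulated
        private = rng.choice(len(free), size=n_private, replace=False)
        for idx in private:
            effects[(c, free[idx])] = rng.choice([-1.0, 1.0]) * effect_size
    return RegulationTruth(effects=effects, mrna_concordance=mrna_concordance)


# ---------------------------------------------------------------------------
# TMT proteome simulation
# ---------------------------------------------------------------------------

def simulate_tmt_experiment(design: ExperimentDesign, truth: RegulationTruth,
                            noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                            batch_sd: float = DEFAULT_BATCH_SD,
                            baseline_mean: float = 20.0,
                            baseline_sd: float = 2.0
                            ) -> tuple[AbundanceMatrix, RegulationTruth]:
    """Simulate a multi-set TMT screen on the log2 scale.

    Each sample value is baseline(protein) + offset(batch, protein) +
    effect(condition, protein) + N(0, noise_sd).  Controls carry no effect,
    so at noise_sd = 0 the knockdown-minus-in-batch-control mean difference
    equals the true effect exactly.  The input truth is echoed back.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth.validate_against(design)
    rng = np.random.default_rng(seed)
    meta = design.sample_meta()
    proteins = design.protein_ids
    n_prot, n_samp = len(proteins), len(meta)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_prot)
    batches = design.batches
    batch_offsets = {b: rng.normal(0.0, batch_sd, size=n_prot) for b in batches}

    effect_mat = np.zeros((n_prot, n_samp))
    prot_pos = {p: i for i, p in enumerate(proteins)}
    col_of_condition: dict[str, list[int]] = {}
    for j, (_, row) in enumerate(meta.iterrows()):
        if not row["is_control"]:
            col_of_condition.setdefault(row["condition"], []).append(j)
    for (cond, prot), eff in truth.effects.items():
        for j in col_of_condition.get(cond, []):
            effect_mat[prot_pos[prot], j] = eff

    values = baseline[:, None] + effect_mat
    for j, (_, row) in enumerate(meta.iterrows()):
        values[:, j] += batch_offsets[row["batch"]]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=proteins, columns=meta.index),
        sample_meta=meta)
    return matrix, truth


# ---------------------------------------------------------------------------
# RNA-seq counterpart
# ---------------------------------------------------------------------------

def simulate_rnaseq_counterpart(truth: RegulationTruth, design: ExperimentDesign,
                                dispersion: float = 0.1, seed: int = 0,
                                ) -> tuple[ExpressionMatrix, dict[tuple[str, str], float]]:
    """TPM matrix mirroring a subset of the protein effects.

    With probability ``mrna_concordance`` a protein effect is carried by its
    gene (same log2 fold-change); otherwise the gene is null.  Multiplicative
    log-normal noise with sigma = ``dispersion`` models biological
    variability; columns are normalised to sum to 1e6.  Returns the matrix
    and the realised (condition, gene) -> effect map of mirrored changes.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    meta = design.sample_meta()
    genes = design.protein_ids.rename("gene")
    n_genes, n_samp = len(genes), len(meta)

    base = rng.lognormal(mean=3.0, sigma=1.5, size=n_genes)
    mirrored = {key: eff for key, eff in sorted(truth.effects.items())
                if rng.random() < truth.mrna_concordance}

    log2_expr = np.log2(base)[:, None] * np.ones((1, n_samp))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cond_cols: dict[str, list[int]] = {}
    for j, (_, row) in enumerate(meta.iterrows()):
        if not row["is_control"]:
            cond_cols.setdefault(row["condition"], []).append(j)
    for (cond, gene), eff in mirrored.items():
        for j in cond_cols.get(cond, []):
            log2_expr[gene_pos[gene], j] += eff

    expr = 2.0 ** log2_expr
    expr *= rng.lognormal(mean=0.0, sigma=dispersion, size=expr.shape)
    expr *= 1e6 / expr.sum(axis=0, keepdims=True)

    matrix = ExpressionMatrix(tpm=pd.DataFrame(expr, index=genes,
                                               columns=meta.index),
                              sample_meta=meta)
    return matrix, mirrored


# ---------------------------------------------------------------------------
# IP-MS spectral counts
# ---------------------------------------------------------------------------

def simulate_ipms_counts(network_truth: list[tuple[str, str, float]],
                         n_bait_reps: int = 3, n_controls: int = 10,
                         contaminants: dict[str, float] | None = None,
                         lengths: dict[str, int] | None = None,
                         seed: int = 0,
                         bait_self_rate: float = 50.0) -> SpectralCountTable:
    """Poisson spectral counts for bait pull-downs and no-bait controls.

    ``network_truth`` lists true edges (bait, prey, mean count): the prey
    receives Poisson counts at that rate in the bait's runs only.
    ``contaminants`` preys receive background Poisson counts in every run
    (their rate approximates a CRAPome-style control frequency source).
    Each bait protein itself is sampled at ``bait_self_rate`` in its own
    runs.  ``lengths`` must cover every protein that can appear.
    """
    if n_bait_reps < 1 or n_controls < 1:
        raise ValueError("need >=1 bait replicate and >=1 control run")
    contaminants = contaminants or {}
    lengths = lengths or {}
    rng = np.random.default_rng(seed)

    baits = sorted({b for b, _, _ in network_truth})
    preys_needed = ({p for _, p, _ in network_truth} | set(contaminants)
                    | set(baits))
    missing = preys_needed - set(lengths)
    if missing:
        raise ValueError(f"prey without a length entry: {sorted(missing)[:5]}")

    edges_of: dict[str, list[tuple[str, float]]] = {b: [] for b in baits}
    for b, p, rate in network_truth:
        if rate < 0:
            raise ValueError("edge rates must be >= 0")
        edges_of[b].append((p, rate))

    rows = []

    def emit(run: str, bait: str, rates: dict[str, float]) -> None:
        for prey in sorted(rates):
            count = int(rng.poisson(rates[prey]))
            if count > 0:
                rows.append((run, bait, prey, count))

    for bait in baits:
        for r in range(1, n_bait_reps + 1):
            rates = dict(contaminants)
            for prey, rate in edges_of[bait]:
                rates[prey] = rates.get(prey, 0.0) + rate
            rates[bait] = rates.get(bait, 0.0) + bait_self_rate
            emit(f"{bait}_r{r}", bait, rates)
    for r in range(1, n_controls + 1):
        emit(f"{CONTROL}_r{r}", CONTROL, dict(contaminants))

    counts = pd.DataFrame(rows, columns=["run", "bait", "prey", "count"])
    # keep empty runs visible as zero-count placeholder rows
    seen_runs = set(counts["run"])
    placeholders = []
    for bait in baits:
        for r in range(1, n_bait_reps + 1):
            run = f"{bait}_r{r}"
            if run not in seen_runs:
                placeholders.append((run, bait, bait, 0))
    for r in range(1, n_controls + 1):
        run = f"{CONTROL}_r{r}"
        if run not in seen_runs:
            anchor = sorted(preys_needed)[0]
            placeholders.append((run, CONTROL, anchor, 0))
    if placeholders:
        counts = pd.concat(
            [counts, pd.DataFrame(placeholders, columns=counts.columns)],
            ignore_index=True)
    return SpectralCountTable(counts=counts,
                              lengths=pd.Series(lengths, name="length"))


# ---------------------------------------------------------------------------
# microscopy scenes
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Additive/counting noise applied to rendered channels."""

    gaussian_sd: float = 0.0
    background: float = 0.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables

    def __post_init__(self) -> None:
        if min(self.gaussian_sd, self.background, self.poisson_scale) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class Punctum:
    """One diffraction-limited spot with per-channel amplitudes."""

    center: tuple[float, float]  # (row, col)
    sigma: float
    amplitude_pts1: float
    amplitude_pmp70: float
    klass: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.klass not in PUNCTUM_CLASSES:
            raise ValueError(f"unknown punctum class {self.klass!r}")
        ok = {
            "functional": self.amplitude_pts1 > 0 and self.amplitude_pmp70 > 0,
            "ghost": self.amplitude_pts1 == 0 and self.amplitude_pmp70 > 0,
            "pts1_only": self.amplitude_pts1 > 0 and self.amplitude_pmp70 == 0,
        }[self.klass]
        if not ok:
            raise ValueError(f"amplitudes inconsistent with class {self.klass!r}")


@dataclass
class SceneTruth:
    """Ground truth of one simulated field: nuclei discs and puncta."""

    image_shape: tuple[int, int]
    nuclei: list[tuple[tuple[float, float], float]]  # (center, radius)
    puncta: list[Punctum]
    pixel_size: float = 0.1  # micrometres per pixel

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise ValueError("image_shape must be at least 16x16")
        for (r, c), rad in self.nuclei:
            if not (0 <= r < h and 0 <= c < w) or rad <= 0:
                raise ValueError("nucleus outside image or non-positive radius")
        for p in self.puncta:
            r, c = p.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError("punctum centre outside image bounds")

    def count(self, klass: str) -> int:
        return sum(1 for p in self.puncta if p.klass == klass)


def render_peroxisome_field(scene: SceneTruth, noise: NoiseModel | None = None,
                            seed: int = 0) -> MultiChannelImage:
    """Render a scene into {nuclei, pts1, pmp70} intensity channels.

    Puncta are isotropic Gaussian spots truncated at 4 sigma (closed-form
    centroids for oracle tests); nuclei are filled discs.  Background and
    Gaussian read noise are added per the noise model; ``poisson_scale``
    converts intensities to photon counts and back for shot noise.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    h, w = scene.image_shape
    channels = {name: np.zeros((h, w)) for name in ("nuclei", "pts1", "pmp70")}

    rr, cc = np.mgrid[0:h, 0:w]
    for (r0, c0), rad in scene.nuclei:
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        channels["nuclei"][disc] += 1000.0

    for p in scene.puncta:
        r0, c0 = p.center
        ext = 4.0 * p.sigma
        r_lo, r_hi = max(0, int(np.floor(r0 - ext))), min(h, int(np.ceil(r0 + ext)) + 1)
        c_lo, c_hi = max(0, int(np.floor(c0 - ext))), min(w, int(np.ceil(c0 + ext)) + 1)
        sub_r, sub_c = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        d2 = (sub_r - r0) ** 2 + (sub_c - c0) ** 2
        spot = np.exp(-d2 / (2.0 * p.sigma**2))
        spot[d2 > ext**2] = 0.0  # hard truncation at 4 sigma
        if p.amplitude_pts1 > 0:
            channels["pts1"][r_lo:r_hi, c_lo:c_hi] += p.amplitude_pts1 * spot
        if p.amplitude_pmp70 > 0:
            channels["pmp70"][r_lo:r_hi, c_lo:c_hi] += p.amplitude_pmp70 * spot

    for name, img in channels.items():
        img = img + noise.background
        if noise.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * noise.poisson_scale
                              ) / noise.poisson_scale
        if noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    return MultiChannelImage(channels=channels, pixel_size=scene.pixel_size)


def random_scene(n_functional: int = 20, n_ghost: int = 10,
                 n_pts1_only: int = 0, n_nuclei: int = 3,
                 image_shape: tuple[int, int] = (256, 256),
                 sigma: float = 1.5, amplitude: float = 1000.0,
                 min_separation: float = 12.0, seed: int = 0,
                 pixel_size: float = 0.1) -> SceneTruth:
    """Scene with a known functional/ghost composition.

    Puncta centres keep ``min_separation`` pixels apart (and clear of the
    border by 4 sigma + 2) so zero-noise rendering segments each spot into
    its own component; nuclei discs sit anywhere in the field.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    margin = 4.0 * sigma + 2.0
    centers: list[tuple[float, float]] = []
    n_total = n_functional + n_ghost + n_pts1_only
    attempts = 0
    while len(centers) < n_total:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place puncta; relax min_separation")
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_separation**2
               for r, c in centers):
            centers.append(cand)

    puncta = []
    for i, center in enumerate(centers):
        if i < n_functional:
            klass, a_pts1, a_pmp70 = "functional", amplitude, amplitude
        elif i < n_functional + n_ghost:
            klass, a_pts1, a_pmp70 = "ghost", 0.0, amplitude
        else:
            klass, a_pts1, a_pmp70 = "pts1_only", amplitude, 0.0
        puncta.append(Punctum(center=center, sigma=sigma, amplitude_pts1=a_pts1,
                              amplitude_pmp70=a_pmp70, klass=klass))

    nuclei = []
    attempts = 0
    while len(nuclei) < n_nuclei:  # keep discs disjoint so counts are exact
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place nuclei; use a larger field")
        cand = (rng.uniform(20, h - 20), rng.uniform(20, w - 20))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= 30.0**2
               for (r, c), _ in nuclei):
            nuclei.append((cand, rng.uniform(8.0, 12.0)))
    return SceneTruth(image_shape=image_shape, nuclei=nuclei, puncta=puncta,
                      pixel_size=pixel_size)
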