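"""Synthetic screen, expression, promoter and network generators with planted truth.

Every generator is a pure function of its arguments (including the seed), so
downstream recovery tests can compare pipeline output against the planted
ground truth under exact reproducibility.

The per-cell morphology model uses a latent-Gaussian construction: each
feature is a fixed monotone transform of a Gaussian whose location carries a
between-well component and, for perturbed wells, a planted shift expressed in
control-SD units of the *well-level aggregate*. Planting on that scale makes
the planted effect equal (to first order) the Z score the scoring stage will
recover, so recovery tests are exact in expectation.

Transforms: areas ``exp(g)`` (lognormal, positive); elongations
``1 + exp(g)`` (axis ratio >= 1); roundness ``logistic(g)`` (in (0,1));
per-well cell counts are negative binomial (overdispersed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import CONTROL_LABEL, MORPHOLOGY_FEATURES

#: EGR2 consensus binding site planted into promoters.
EGR2_CONSENSUS = "ACGCCCACGCA"

#: Directional reversal signature: expected Z sign under senescence reversal.
REVERSAL_SIGNATURE = {
    "cell_count": +1,
    "cell_area": -1,
    "nuclear_area": -1,
    "nuclear_elongation": -1,
    "nuclear_roundness": +1,
    "cell_elongation": +1,
}

SIX_CATEGORIES = (
    "immune response",
    "cell adhesion/cytoskeleton",
    "metabolism",
    "transcription",
    "growth/proliferation",
    "protein/vesicle trafficking",
)

_TRANSFORMS = {
    "cell_area": "exp",
    "nuclear_area": "exp",
    "cell_elongation": "one_plus_exp",
    "nuclear_elongation": "one_plus_exp",
    "cell_roundness": "logistic",
    "nuclear_roundness": "logistic",
}


@dataclass(frozen=True)
class FeatureParams:
    """Latent-Gaussian parameters for one morphology feature.

    loc: latent location (transform of loc gives the typical cell value).
    cell_sd: latent cell-to-cell SD within a well.
    well_sd: latent well-to-well SD (plate-to-plate variation is not modelled).
    """

    loc: float
    cell_sd: float
    well_sd: float

    def __post_init__(self):
        if self.cell_sd <= 0 or self.well_sd <= 0:
            raise ValueError("distribution scales must be > 0")


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-phenotype distribution parameters for all seven features."""

    cell_count_mean: float
    cell_count_dispersion: float  # NB size parameter; var = m + m^2/k
    features: dict[str, FeatureParams]

    def __post_init__(self):
        if self.cell_count_mean <= 0 or self.cell_count_dispersion <= 0:
            raise ValueError("cell count parameters must be > 0")
        missing = set(MORPHOLOGY_FEATURES) - set(self.features)
        if missing:
            raise ValueError(f"missing feature parameters: {sorted(missing)}")

    def count_sd(self) -> float:
        m, k = self.cell_count_mean, self.cell_count_dispersion
        return math.sqrt(m + m * m / k)

    def latent_well_sd(self, feature: str) -> float:
        """SD of the well-level latent median over control wells.

        Combines between-well variation with the sampling noise of the median
        of ~n cells (asymptotic variance pi*sigma^2/(2n) for a Gaussian).
        """
        fp = self.features[feature]
        n = self.cell_count_mean
        return math.sqrt(fp.well_sd**2 + math.pi * fp.cell_sd**2 / (2 * n))


def _pheno(count_mean, count_k, **feats) -> PhenotypeParams:
    return PhenotypeParams(
        cell_count_mean=count_mean,
        cell_count_dispersion=count_k,
        features={k: FeatureParams(*v) for k, v in feats.items()},
    )


# Early-proliferating (EP), deeply senescent (DS) and reversed (R) defaults.
# DS cells are larger (cell/nuclear area up), sparser (count down), with more
# elongated, less round nuclei and less elongated cell bodies than EP; the
# reversed phenotype sits close to EP.
DEFAULT_PARAMS: dict[str, PhenotypeParams] = {
    "EP": _pheno(
        140.0, 50.0,
        cell_area=(math.log(1800.0), 0.40, 0.05),
        nuclear_area=(math.log(180.0), 0.35, 0.05),
        cell_elongation=(math.log(0.80), 0.50, 0.06),
        nuclear_elongation=(math.log(0.25), 0.40, 0.06),
        cell_roundness=(0.0, 0.8, 0.08),
        nuclear_roundness=(1.8, 0.7, 0.08),
    ),
    "DS": _pheno(
        70.0, 50.0,
        cell_area=(math.log(4200.0), 0.40, 0.05),
        nuclear_area=(math.log(320.0), 0.35, 0.05),
        cell_elongation=(math.log(0.45), 0.50, 0.06),
        nuclear_elongation=(math.log(0.55), 0.40, 0.06),
        cell_roundness=(0.6, 0.8, 0.08),
        nuclear_roundness=(0.85, 0.7, 0.08),
    ),
    "reversed": _pheno(
        130.0, 50.0,
        cell_area=(math.log(2000.0), 0.40, 0.05),
        nuclear_area=(math.log(195.0), 0.35, 0.05),
        cell_elongation=(math.log(0.75), 0.50, 0.06),
        nuclear_elongation=(math.log(0.28), 0.40, 0.06),
        cell_roundness=(0.05, 0.8, 0.08),
        nuclear_roundness=(1.7, 0.7, 0.08),
    ),
}

# DS-vs-EP ordering sanity (senescent direction): checked at import time.
assert DEFAULT_PARAMS["DS"].features["cell_area"].loc > DEFAULT_PARAMS["EP"].features["cell_area"].loc
assert DEFAULT_PARAMS["DS"].features["nuclear_area"].loc > DEFAULT_PARAMS["EP"].features["nuclear_area"].loc
assert DEFAULT_PARAMS["DS"].cell_count_mean < DEFAULT_PARAMS["EP"].cell_count_mean

TEST_ARMS = ("Group1", "Group1B", "Group2", "Group3")

DEFAULT_DOSES = {
    "Group1": 30.0,
    "Group1B": 60.0,
    "Group2": 15.0,
    "Group3": 15.0,
    "control": 30.0,
}


@dataclass(frozen=True)
class EffectMap:
    """Planted siRNA effects, in control-SD units of the well-level aggregate.

    shifts: siRNA id -> {feature -> signed shift}. ``cell_count`` shifts act
    on the negative-binomial mean; morphology shifts act on the latent scale.
    arms: siRNA id -> arms in which the effect is active (default: all).
    dose_factor: multiplier applied in the high-dose Group1B arm.
    """

    shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    arms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    dose_factor: float = 1.5

    def __post_init__(self):
        for sirna, fs in self.shifts.items():
            for feat, v in fs.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite shift for {sirna}/{feat}")

    def shift(self, sirna: str, arm: str) -> dict[str, float]:
        if sirna not in self.shifts:
            return {}
        if arm not in self.arms.get(sirna, TEST_ARMS):
            return {}
        scale = self.dose_factor if arm == "Group1B" else 1.0
        return {f: v * scale for f, v in self.shifts[sirna].items()}

    def is_reverser(self, sirna: str, arm: str) -> bool:
        """True when the active shift moves every signature feature the
        reversal way."""
        s = self.shift(sirna, arm)
        if not s:
            return False
        return all(
            f in s and s[f] * sign > 0 for f, sign in REVERSAL_SIGNATURE.items()
        )


def reversal_effect(magnitude: float) -> dict[str, float]:
    """Per-feature shifts of |magnitude| SD in the reversal direction."""
    return {f: sign * magnitude for f, sign in REVERSAL_SIGNATURE.items()}


@dataclass(frozen=True)
class LayoutSpec:
    """Plate/replicate/arm design: one 384-well plate per (arm, replicate)."""

    arms: tuple[str, ...] = ("Group1",)
    replicates: int = 3
    controls_per_plate: int = 16
    doses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOSES))


_ROWS = "ABCDEFGHIJKLMNOP"


def _well_name(i: int) -> str:
    return f"{_ROWS[i // 24]}{i % 24 + 1}"


def generate_screen(
    library: list[str],
    layout_spec: LayoutSpec,
    params: dict[str, PhenotypeParams],
    effects: EffectMap,
    seed: int,
    phenotype: str = "DS",
):
    """Simulate a 384-well high-content siRNA screen.

    Returns ``(cells, layout, truth)``: a per-cell feature table, the matching
    plate layout, and a truth table recording the planted shift and reverser
    status of every (siRNA, arm).
    """
    if not library:
        raise ValueError("siRNA library is empty")
    if len(set(library)) != len(library):
        raise ValueError("duplicate siRNA ids in library")
    if layout_spec.replicates < 2:
        raise ValueError("at least 2 replicates required")
    if layout_spec.controls_per_plate < 8:
        raise ValueError(
            f"plate design for arm {layout_spec.arms[0]!r} has "
            f"{layout_spec.controls_per_plate} control wells; >= 8 required"
        )
    base = params[phenotype]
    n_total = len(library) + layout_spec.controls_per_plate
    if n_total > 384:
        raise ValueError(f"{n_total} wells exceed the 384-well plate")

    # control wells spread evenly across the used portion of the plate
    ctrl_idx = set(
        int(round(x))
        for x in np.linspace(0, n_total - 1, layout_spec.controls_per_plate)
    )

    layout_rows, cell_frames = [], []
    plates = [
        (arm, rep) for arm in layout_spec.arms for rep in range(1, layout_spec.replicates + 1)
    ]
    for plate_i, (arm, rep) in enumerate(plates):
        plate = f"{arm}_r{rep}"
        rng = np.random.default_rng([seed % (2**31), plate_i])
        lib_iter = iter(library)
        for w in range(n_total):
            well = _well_name(w)
            if w in ctrl_idx:
                sirna, well_arm, dose = CONTROL_LABEL, "control", layout_spec.doses["control"]
            else:
                sirna, well_arm, dose = next(lib_iter), arm, layout_spec.doses[arm]
            layout_rows.append((plate, well, sirna, dose, well_arm, rep))
            shift = effects.shift(sirna, well_arm) if well_arm != "control" else {}
            cell_frames.append(
                _simulate_well(plate, well, base, shift, rng)
            )

    layout = pd.DataFrame(
        layout_rows,
        columns=["plate", "well", "sirna", "dose_nM", "arm", "replicate"],
    )
    cells = pd.concat(cell_frames, ignore_index=True)

    truth_rows = []
    for arm in layout_spec.arms:
        for sirna in library:
            shift = effects.shift(sirna, arm)
            truth_rows.append(
                {
                    "sirna": sirna,
                    "arm": arm,
                    "is_reverser": effects.is_reverser(sirna, arm),
                    **{f"shift_{f}": shift.get(f, 0.0) for f in ("cell_count", *MORPHOLOGY_FEATURES)},
                }
            )
    truth = pd.DataFrame(truth_rows)
    return cells, layout, truth


def _simulate_well(plate, well, pheno: PhenotypeParams, shift, rng) -> pd.DataFrame:
    mean = pheno.cell_count_mean + shift.get("cell_count", 0.0) * pheno.count_sd()
    mean = max(mean, 0.5)
    k = pheno.cell_count_dispersion
    n = int(rng.negative_binomial(k, k / (k + mean)))
    data = {"plate": plate, "well": well, "cell_index": np.arange(n)}
    for feat in MORPHOLOGY_FEATURES:
        fp = pheno.features[feat]
        loc = fp.loc + rng.normal(0.0, fp.well_sd)
        loc += shift.get(feat, 0.0) * pheno.latent_well_sd(feat)
        g = rng.normal(loc, fp.cell_sd, size=n)
        kind = _TRANSFORMS[feat]
        if kind == "exp":
            data[feat] = np.exp(g)
        elif kind == "one_plus_exp":
            data[feat] = 1.0 + np.exp(g)
        else:  # logistic
            data[feat] = 1.0 / (1.0 + np.exp(-g))
    return pd.DataFrame(data)


def hmf_screen_design(magnitude: float = 4.0):
    """Planted design of the three-arm fibroblast reversal screen.

    A 60-siRNA library (27 regulators + 33 interactors) with one Group1
    reverser (the EGR2 analogue, also a Group3 hit), two Group2-only hits,
    and 45 Group3 hits in total (21 regulators + 24 interactors). Returns
    ``(library, EffectMap)``.
    """
    regulators = [f"REG{i + 1:02d}" for i in range(27)]
    interactors = [f"INT{i + 1:02d}" for i in range(33)]
    shifts: dict[str, dict[str, float]] = {}
    arms: dict[str, tuple[str, ...]] = {}
    shifts[regulators[0]] = reversal_effect(magnitude)
    arms[regulators[0]] = ("Group1", "Group3")
    for r in regulators[1:21]:
        shifts[r] = reversal_effect(magnitude)
        arms[r] = ("Group3",)
    for g in interactors[:24]:
        shifts[g] = reversal_effect(magnitude)
        arms[g] = ("Group3",)
    for g in interactors[24:26]:
        shifts[g] = reversal_effect(magnitude)
        arms[g] = ("Group2",)
    return regulators + interactors, EffectMap(shifts=shifts, arms=arms)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int,
    n_up_in_DS: int,
    effect_size: float,
    n_reps: int,
    seed: int,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    residual_sd: float = 0.25,
    revert_fraction: float = 1.0,
):
    """Simulate a log-scale gene x sample matrix over EP/DS/Reversed.

    Planted genes get a DS mean raised by ``effect_size`` residual-SD units
    and a Reversed mean pulled back toward EP by ``revert_fraction`` of the
    rise; all other genes are exchangeable across conditions.

    Returns ``(ExpressionMatrix, planted gene list)``.
    """
    from .expression import ExpressionMatrix  # local import to avoid a cycle

    if n_up_in_DS > n_genes:
        raise ValueError("n_up_in_DS cannot exceed n_genes")
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed % (2**31))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted = genes[:n_up_in_DS]

    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    delta = effect_size * residual_sd
    means = {
        "EP": base,
        "DS": base + np.where(np.arange(n_genes) < n_up_in_DS, delta, 0.0),
        "R": base
        + np.where(np.arange(n_genes) < n_up_in_DS, delta * (1 - revert_fraction), 0.0),
    }
    cols, values = [], []
    for cond in ("EP", "DS", "R"):
        for r in range(1, n_reps + 1):
            cols.append(f"{cond}_{r}")
            values.append(means[cond] + rng.normal(0.0, residual_sd, size=n_genes))
    df = pd.DataFrame(np.column_stack(values), index=genes, columns=cols)
    conditions = pd.Series({c: c.split("_")[0] for c in cols})
    return ExpressionMatrix(df, conditions), planted


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def generate_promoters(
    genes: list[str],
    length: int,
    plant: dict[str, int],
    gc: float = 0.5,
    seed: int = 0,
    motif: str = EGR2_CONSENSUS,
    ensure_motif_free: bool = False,
) -> list[tuple[str, str]]:
    """Generate promoter FASTA records with planted motif copies.

    Each record is i.i.d. background at the given GC fraction with the
    requested number of motif copies inserted at non-overlapping random
    positions on random strands. With ``ensure_motif_free`` the background is
    redrawn until it carries no spurious exact match, so planted counts are
    exact; otherwise background matches arise at the closed-form rate.
    """
    from .motif import reverse_complement  # shared helper

    L = len(motif)
    if length < L:
        raise ValueError("promoter length shorter than the motif")
    if any(v < 0 for v in plant.values()):
        raise ValueError("plant counts must be >= 0")
    rng = np.random.default_rng(seed % (2**31))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    records = []
    for gene in genes:
        copies = plant.get(gene, 0)
        if copies * L > length:
            raise ValueError(
                f"{copies} motif copies cannot fit in {length} bp for {gene}"
            )
        for _ in range(200):
            seq = rng.choice(bases, size=length, p=probs)
            if not ensure_motif_free:
                break
            s = "".join(seq)
            if motif not in s and reverse_complement(motif) not in s:
                break
        else:
            raise RuntimeError("could not draw a motif-free background")
        positions = _place_nonoverlapping(copies, length, L, rng, gene)
        for pos in positions:
            ins = motif if rng.random() < 0.5 else reverse_complement(motif)
            seq[pos : pos + L] = list(ins)
        records.append((gene, "".join(seq)))
    return records


def _place_nonoverlapping(copies, length, L, rng, gene):
    positions: list[int] = []
    for _ in range(copies):
        for _ in range(1000):
            pos = int(rng.integers(0, length - L + 1))
            if all(abs(pos - p) >= L for p in positions):
                positions.append(pos)
                break
        else:
            raise ValueError(
                f"could not place {copies} non-overlapping motif copies for {gene}"
            )
    return positions


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

def generate_network(
    seeds: list[str],
    n_interactors: int,
    extra_edges: int = 0,
    seed: int = 0,
    unassigned_fraction: float = 0.15,
):
    """Generate a BioGRID-like edge list around seed genes, plus annotation.

    Exactly ``n_interactors`` distinct non-seed genes are made adjacent to at
    least one seed; ``extra_edges`` attach second-degree distractor genes that
    a depth-1 expansion must not pick up. The annotation table assigns each
    gene one of the six functional categories or "unassigned".
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seed ids")
    if n_interactors < 0:
        raise ValueError("n_interactors must be >= 0")
    rng = np.random.default_rng(seed % (2**31))
    edges: set[frozenset] = set()
    interactors = [f"INT{i + 1:04d}" for i in range(n_interactors)]
    for gene in interactors:
        n_links = int(rng.integers(1, min(3, len(seeds)) + 1))
        for s in rng.choice(seeds, size=n_links, replace=False):
            edges.add(frozenset((gene, str(s))))
    anchors = interactors if interactors else None
    for i in range(extra_edges):
        distal = f"EXT{i + 1:04d}"
        if anchors:
            edges.add(frozenset((distal, str(rng.choice(anchors)))))
        else:
            edges.add(frozenset((distal, f"EXT{i + 2:04d}")))

    all_genes = sorted({g for e in edges for g in e} | set(seeds))
    annotation = {}
    for gene in all_genes:
        if rng.random() < unassigned_fraction:
            annotation[gene] = "unassigned"
        else:
            annotation[gene] = SIX_CATEGORIES[int(rng.integers(len(SIX_CATEGORIES)))]
    return sorted(edges, key=lambda e: tuple(sorted(e))), annotation
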