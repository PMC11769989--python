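"""Synthetic cross-species diurnal RNA-seq studies with known ground truth.

The generator emulates the two study designs the downstream pipeline is
built for:

* **mouse** — animals sacrificed on a fixed zeitgeber grid (default
  ZT 2, 6, 10, 14, 18, 22) with ``n_per_sex_time`` animals per sex per
  timepoint, i.e. a balanced 6-timepoint design;
* **human** — postmortem cohorts with a continuous time of death
  (hours after sunrise), ``n_per_sex`` subjects per sex in each of one
  or more cortical subregions.

Counts are negative binomial around a log2-scale sinusoid: for gene g in
sample s at time t,

    mu_gs = L_s * x_gs / sum_g x_gs,   x_gs = 2^(m_g + A_g cos(2*pi*(t - phi_g)/24))

where L_s is the sample's library size, m_g the mesor, A_g the log2
amplitude (0 for non-rhythmic genes) and phi_g the peak time. The
normalisation by the per-sample total makes L_s the expected library
size. Overdispersion uses a single dispersion alpha with
Var = mu + alpha * mu^2.

A designated block of conserved clock genes (PER1-3, DBP, CIART, NR1D1,
CHRM4, KANSL3) is rhythmic in every group and peaks in humans at the
mouse peak plus a per-sex species offset (default -12 h in males, -9 h
in females), mimicking the anti-phase relationship between a nocturnal
and a diurnal species. Y-flagged and very low-expressed genes are
included so the expression filter has something to remove.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, SampleTable

CLOCK_GENES = ("CHRM4", "CIART", "DBP", "KANSL3", "NR1D1", "PER1", "PER2", "PER3")

#: distribution specs are tuples: ("uniform", lo, hi), ("point", v),
#: ("bimodal", peak1, peak2, weight1, kappa) for phases (wrapped-normal-ish
#: mixture implemented as normal around each peak, mod 24).
DistSpec = tuple


def _draw(spec: DistSpec, size, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=size)
    if kind == "point":
        return np.full(size, float(spec[1]))
    raise ValidationError(f"unknown distribution spec {spec!r}")


def _draw_phase(spec: DistSpec, size, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        lo = float(spec[1]) if len(spec) > 1 else 0.0
        hi = float(spec[2]) if len(spec) > 2 else 24.0
        return rng.uniform(lo, hi, size=size) % 24.0
    if kind == "point":
        return np.full(size, float(spec[1]) % 24.0)
    if kind == "bimodal":
        peak1, peak2, w1 = float(spec[1]), float(spec[2]), float(spec[3])
        sd = float(spec[4]) if len(spec) > 4 else 1.5
        pick = rng.random(size) < w1
        centers = np.where(pick, peak1, peak2)
        return (centers + rng.normal(0.0, sd, size=size)) % 24.0
    raise ValidationError(f"unknown phase distribution spec {spec!r}")


@dataclass
class MouseDesign:
    """Balanced zeitgeber-grid design."""

    timepoints: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
    n_per_sex_time: int = 5
    region: str = "mPFC"
    phase_dist: DistSpec | None = None  # overrides config.phase_dist

    def __post_init__(self) -> None:
        if not all(0.0 <= t < 24.0 for t in self.timepoints):
            raise ValidationError("mouse timepoints must lie in [0, 24)")
        if self.n_per_sex_time < 1:
            raise ValidationError("n_per_sex_time must be >= 1")


@dataclass
class HumanDesign:
    """Continuous time-of-death cohort design, per subregion."""

    regions: tuple[str, ...] = ("DLPFC", "ACC")
    n_per_sex: dict = field(default_factory=lambda: {"DLPFC": 42, "ACC": 38})
    tod_dist: DistSpec = ("uniform", 0.0, 24.0)
    phase_dist: DistSpec | None = None

    def __post_init__(self) -> None:
        for r in self.regions:
            if self.n_per_sex.get(r, 0) < 1:
                raise ValidationError(f"n_per_sex missing or < 1 for region {r!r}")


@dataclass
class SimulationConfig:
    """Study-level simulation parameters (defaults = the emulated designs)."""

    n_genes: int = 2000
    frac_rhythmic: float = 0.12
    amplitude_log2: DistSpec = ("uniform", 0.5, 2.0)
    phase_dist: DistSpec = ("uniform", 0.0, 24.0)
    mesor_log2: DistSpec = ("uniform", 3.0, 8.0)
    nb_dispersion: float = 0.1
    library_size: DistSpec = ("uniform", 4.0e6, 6.0e6)
    mouse: MouseDesign | None = field(default_factory=MouseDesign)
    human: HumanDesign | None = field(default_factory=HumanDesign)
    #: human peak minus mouse peak for the conserved clock block, per sex
    species_phase_offset_h: dict = field(
        default_factory=lambda: {"M": -12.0, "F": -9.0}
    )
    clock_genes: tuple[str, ...] = CLOCK_GENES
    clock_amplitude_log2: float = 1.5
    #: mouse peak times of the clock block: clock-output genes peak in the
    #: late light / early dark phase; keeping them there also keeps the raw
    #: human-minus-mouse differences away from the +/-12 h fold
    clock_mouse_phase_dist: DistSpec = ("uniform", 14.0, 18.0)
    #: of the non-clock rhythmic pool, fraction rhythmic in BOTH species
    frac_shared_rhythmic: float = 0.25
    frac_y_chromosome: float = 0.005
    frac_low_expressed: float = 0.05
    #: target counts-per-million for low-expressed genes; their mesor is
    #: derived from this so they sit below the CPM>1 filter regardless of
    #: how many genes the study simulates
    low_cpm: DistSpec = ("uniform", 0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for name in ("frac_rhythmic", "frac_shared_rhythmic", "frac_y_chromosome",
                     "frac_low_expressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.mouse is None and self.human is None:
            raise ValidationError("at least one of mouse/human design required")
        if self.clock_genes and round(self.n_genes * self.frac_rhythmic) < len(
            self.clock_genes
        ):
            raise ValidationError(
                "rhythmic fraction too small to contain the clock-gene block"
            )


def sample_times(design, rng: np.random.Generator, region: str | None = None,
                 n: int | None = None) -> np.ndarray:
    """Per-sample times for one sex of a design.

    Mouse designs repeat the configured ZT grid exactly; human designs
    draw from the time-of-death distribution (``n`` overrides the
    region's cohort size; ``region`` defaults to the first).
    """
    if isinstance(design, MouseDesign):
        return np.repeat(np.asarray(design.timepoints, float), design.n_per_sex_time)
    if isinstance(design, HumanDesign):
        if n is None:
            region = region if region is not None else design.regions[0]
            n = design.n_per_sex[region]
        return _draw(design.tod_dist, n, rng) % 24.0
    raise ValidationError(f"unknown design {design!r}")


def _human_times(design: HumanDesign, region: str, rng: np.random.Generator) -> np.ndarray:
    return sample_times(design, rng, region=region)


@dataclass
class TruthTable:
    """Per-gene, per-group simulation ground truth.

    Columns: gene_id, group (species_sex_region), is_rhythmic, mesor,
    amplitude, peak_time_h. Non-rhythmic rows have amplitude 0.
    """

    frame: pd.DataFrame

    def rhythmic_genes(self, group: str | None = None) -> set[str]:
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        return set(df.loc[df["is_rhythmic"], "gene_id"])

    def n_rhythmic(self) -> int:
        """Number of genes rhythmic in at least one group."""
        return len(self.rhythmic_genes())


def _gene_names(n: int, clock: tuple[str, ...]) -> list[str]:
    width = max(5, len(str(n)))
    names = [f"G{i:0{width}d}" for i in range(n)]
    for i, g in enumerate(clock[: n]):
        names[i] = g
    return names


def generate_study(config: SimulationConfig, seed: int | None = None):
    """Simulate one cross-species study.

    Returns ``(ExpressionMatrix, SampleTable, TruthTable)``; the matrix
    holds raw counts for all species' samples over a shared gene
    universe. Deterministic in ``(config, seed)``; ``seed=None`` uses
    ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_genes
    genes = _gene_names(n, config.clock_genes)
    n_clock = min(len(config.clock_genes), n)
    clock_idx = np.arange(n_clock)

    # --- gene-level truth ------------------------------------------------
    mesor = _draw(config.mesor_log2, n, rng)
    n_low = round(n * config.frac_low_expressed)
    non_clock = np.arange(n_clock, n)
    low_idx = rng.choice(non_clock, size=min(n_low, len(non_clock)), replace=False)
    # pin low-expressed genes to a target CPM (their own mass is negligible)
    high = np.setdiff1d(np.arange(n), low_idx)
    total_x = np.exp2(mesor[high]).sum()
    target_cpm = _draw(config.low_cpm, len(low_idx), rng)
    mesor[low_idx] = np.log2(target_cpm * total_x / (1.0e6 - target_cpm * len(low_idx)))

    n_y = round(n * config.frac_y_chromosome)
    y_pool = np.setdiff1d(non_clock, low_idx)
    y_idx = rng.choice(y_pool, size=min(n_y, len(y_pool)), replace=False)

    # rhythmic pool: exactly round(n * frac_rhythmic) genes, clock first
    m = round(n * config.frac_rhythmic)
    extra_pool = np.setdiff1d(non_clock, low_idx)  # keep low genes arrhythmic
    extra = rng.choice(extra_pool, size=max(0, m - n_clock), replace=False)
    n_shared = round(config.frac_shared_rhythmic * len(extra))
    shared = extra[:n_shared]
    rest = extra[n_shared:]
    half = len(rest) // 2
    mouse_only, human_only = rest[:half], rest[half:]

    species_present = [s for s, d in (("mouse", config.mouse), ("human", config.human)) if d]
    rhythmic_in: dict[str, np.ndarray] = {}
    for sp in species_present:
        own = mouse_only if sp == "mouse" else human_only
        rhythmic_in[sp] = np.concatenate([clock_idx, shared, own]).astype(int)

    # per-(gene, species) amplitude and phase; clock block gets sex-specific
    # human phases offset from the mouse phase
    amp: dict[str, np.ndarray] = {}
    phase: dict[tuple[str, str], np.ndarray] = {}  # (species, sex) -> per-gene
    mouse_phase_spec = (
        (config.mouse.phase_dist if config.mouse and config.mouse.phase_dist else config.phase_dist)
    )
    human_phase_spec = (
        (config.human.phase_dist if config.human and config.human.phase_dist else config.phase_dist)
    )
    clock_mouse_phase = _draw_phase(config.clock_mouse_phase_dist, n_clock, rng)
    for sp in species_present:
        a = np.zeros(n)
        a[rhythmic_in[sp]] = _draw(config.amplitude_log2, len(rhythmic_in[sp]), rng)
        a[clock_idx] = config.clock_amplitude_log2
        amp[sp] = a
        spec = mouse_phase_spec if sp == "mouse" else human_phase_spec
        base = _draw_phase(spec, n, rng)
        for sex in ("M", "F"):
            ph = base.copy()
            if sp == "mouse":
                ph[clock_idx] = clock_mouse_phase
            else:
                off = float(config.species_phase_offset_h.get(sex, 0.0))
                ph[clock_idx] = (clock_mouse_phase + off) % 24.0
            phase[(sp, sex)] = ph

    # --- samples ---------------------------------------------------------
    rows = []  # (sample_id, species, sex, region, time_h)
    for sex in ("M", "F"):
        if config.mouse:
            for t in sample_times(config.mouse, rng):
                rows.append(("mouse", sex, config.mouse.region, float(t)))
    for sex in ("M", "F"):
        if config.human:
            for region in config.human.regions:
                for t in _human_times(config.human, region, rng):
                    rows.append(("human", sex, region, float(t)))
    meta = pd.DataFrame(rows, columns=["species", "sex", "region", "time_h"])
    meta.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(meta))])

    # --- counts ----------------------------------------------------------
    lib = _draw(config.library_size, len(meta), rng)
    counts = np.empty((n, len(meta)), dtype=np.int64)
    omega = 2.0 * np.pi / 24.0
    disp = config.nb_dispersion
    r_nb = 1.0 / disp
    for j, srow in enumerate(meta.itertuples(index=False)):
        key = (srow.species, srow.sex)
        log2x = mesor + amp[srow.species] * np.cos(omega * (srow.time_h - phase[key]))
        x = np.exp2(log2x)
        mu = lib[j] * x / x.sum()
        p_nb = r_nb / (r_nb + mu)
        counts[:, j] = rng.negative_binomial(r_nb, p_nb)

    values = pd.DataFrame(counts, index=genes, columns=meta["sample_id"])
    chrom = np.where(np.isin(np.arange(n), y_idx), "Y", "autosome")
    ann = pd.DataFrame({"chromosome": chrom}, index=genes)
    expr = ExpressionMatrix(values, value_kind="raw_counts", gene_annotations=ann)
    samples = SampleTable(meta)

    # --- truth table ------------------------------------------------------
    truth_rows = []
    for sp in species_present:
        design = config.mouse if sp == "mouse" else config.human
        regions = [design.region] if sp == "mouse" else list(design.regions)
        is_r = np.zeros(n, dtype=bool)
        is_r[rhythmic_in[sp]] = True
        for sex in ("M", "F"):
            ph = phase[(sp, sex)]
            for region in regions:
                group = f"{sp}_{sex}_{region}"
                truth_rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": genes,
                            "group": group,
                            "is_rhythmic": is_r,
                            "mesor": mesor,
                            "amplitude": np.where(is_r, amp[sp], 0.0),
                            "peak_time_h": np.where(is_r, ph, np.nan),
                        }
                    )
                )
    truth = TruthTable(pd.concat(truth_rows, ignore_index=True))
    return expr, samples, truth
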