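"""Synthetic multiplexed-assay generator.

Emulates the two selection experiments run on a barcoded saturation
mutagenesis library of a short single-pass membrane protein:

* a 4-bin FACS sort-seq experiment in which each cell's surface
  fluorescence is a noisy readout of its variant's latent surface
  expression ``tau`` and the pool is split at population quartiles, and
* a day-0/8/20 depletion experiment in which cells carrying a variant
  with latent functional activity ``phi`` are lost at a rate
  proportional to ``phi`` (functional channels cost fitness under the
  gain-of-function selection background).

Both experiments are read out by multinomial sequencing of barcode
pools to a fixed per-sample depth, so simulated count-matrix columns
sum exactly to ``reads_per_sample``.  A single seed drives independent
substreams for library construction, sorting, and depletion, making
every output reproducible.

The module also houses the library-design primer-melting-temperature
helper (Wallace rule), since primer design is part of constructing the
mutagenesis library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .variants import ReferenceModel, enumerate_site_outcomes

_SENSE_CODONS = [
    "GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTG",
    "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT",
]


def primer_tm(seq: str) -> int:
    """Wallace-rule melting temperature: ``4*(G+C) + 2*(A+T)`` degrees C.

    The crude counting formula used to design mutagenesis primers
    (target Tm 58 degrees in the library design this emulates).
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in primer: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    return 4 * gc + 2 * (len(seq) - gc)


@dataclass(frozen=True)
class EffectModel:
    """Per-class distributions of the latent effects.

    Each latent is anchored so synonymous variants sit near 1 and severe
    loss near 0.  Components are (mean, sd) of a normal clipped at 0;
    missense mixtures are ``{label: (weight, mean, sd)}``.  Nonsense
    variants switch from a loss-like to a WT-like component after the
    regime boundary (residue 55 for surface expression, 104 for
    function).  Non-synonymous variants at residue 1 destroy the start
    codon and are forced into the loss component of both latents.
    """

    syn_tau: tuple[float, float] = (1.0, 0.08)
    syn_phi: tuple[float, float] = (1.0, 0.20)
    nonsense_early_tau: tuple[float, float] = (0.02, 0.03)
    nonsense_late_tau: tuple[float, float] = (0.90, 0.12)
    nonsense_early_phi: tuple[float, float] = (0.02, 0.03)
    nonsense_late_phi: tuple[float, float] = (1.0, 0.15)
    trafficking_boundary: int = 55
    functional_boundary: int = 104
    missense_tau_mix: dict = field(
        default_factory=lambda: {
            "loss": (0.05, 0.02, 0.03),
            "partial": (0.15, 0.50, 0.12),
            "normal": (0.67, 1.00, 0.08),
            "gain": (0.13, 1.35, 0.10),
        }
    )
    missense_phi_mix: dict = field(
        default_factory=lambda: {
            "loss": (0.075, 0.05, 0.04),
            "partial": (0.175, 0.25, 0.08),
            "normal": (0.75, 1.00, 0.20),
        }
    )
    #: loss-of-surface-expression variants are usually also nonfunctional
    p_phi_loss_given_tau_loss: float = 0.8


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic assays.

    Defaults mirror the emulated experiment: a 129-residue protein,
    ~95.7% of the 21-per-site outcome space present in the library, a
    mean of 30.7 random 18-mer barcodes per variant, triplicates, four
    sort bins of ~25% occupancy, days 0/8/20, and a selection strength
    under which a WT-like variant depletes ~10-fold by day 20.
    """

    protein_length: int = 129
    n_barcodes_mean: float = 30.7
    barcode_length: int = 18
    n_replicates: int = 3
    reads_per_sample: int = 1_000_000
    bin_count: int = 4
    effect_model: EffectModel = field(default_factory=EffectModel)
    fluorescence_sd: float = 0.6
    background_fluorescence: float = 0.05
    growth_coupling: float = float(np.log(10) / 20.0)  # per unit activity per day
    days: tuple[int, ...] = (0, 8, 20)
    cells_per_replicate: int = 3_200_000
    abundance_sd: float = 0.3
    library_coverage: float = 0.957
    barcode_dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "protein_length", "barcode_length", "n_replicates",
            "reads_per_sample", "cells_per_replicate",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.bin_count != 4:
            raise ValueError("bin_count is fixed at 4")
        if self.n_barcodes_mean <= 0:
            raise ValueError("n_barcodes_mean must be positive")
        if not 0 < self.library_coverage <= 1:
            raise ValueError("library_coverage must be in (0, 1]")
        days = tuple(self.days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing and start at 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream (0 library, 1 sort-seq, 2 depletion)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])


def random_reference(protein_length: int, rng: np.random.Generator) -> ReferenceModel:
    """A random stop-free CDS starting with ATG (residue 1 is Met)."""
    codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=protein_length - 1))
    return ReferenceModel.from_cds("".join(codons))


def _draw(rng: np.random.Generator, params: tuple[float, float], n: int) -> np.ndarray:
    mean, sd = params
    return np.clip(rng.normal(mean, sd, size=n), 0.0, None)


def _draw_mixture(rng: np.random.Generator, mix: dict, n: int):
    labels = list(mix)
    weights = np.array([mix[k][0] for k in labels], dtype=float)
    weights = weights / weights.sum()
    which = rng.choice(len(labels), size=n, p=weights)
    values = np.empty(n)
    for i, lab in enumerate(labels):
        sel = which == i
        values[sel] = _draw(rng, mix[lab][1:], int(sel.sum()))
    return np.array(labels, dtype=object)[which], values


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if n > 4 ** length / 2:
        raise ValueError("barcode space exhausted")
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = ["".join(row) for row in bases[rng.integers(0, 4, size=(n - len(out), length))]]
        for bc in block:  # collisions resolved by redraw on the next pass
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_library(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the barcoded variant library and its ground truth.

    Returns ``(barcode_map, truth)``: ``barcode_map`` maps each unique
    barcode to a variant name; ``truth`` holds, per variant, the latent
    surface expression ``tau`` and activity ``phi`` with their component
    labels, plus a reference row (``vclass == 'reference'``) carried in
    the generated CDS.
    """
    rng = cfg.rng(0)
    em = cfg.effect_model
    ref = random_reference(cfg.protein_length, rng)
    outcomes = enumerate_site_outcomes(ref.protein)
    n_keep = int(round(cfg.library_coverage * len(outcomes)))
    keep = np.sort(rng.choice(len(outcomes), size=n_keep, replace=False))
    outcomes = outcomes.iloc[keep].reset_index(drop=True)

    n = len(outcomes)
    pos = outcomes["position"].to_numpy()
    vclass = outcomes["vclass"].to_numpy()
    tau = np.empty(n)
    phi = np.empty(n)
    tau_class = np.empty(n, dtype=object)
    phi_class = np.empty(n, dtype=object)

    syn = vclass == "synonymous"
    tau[syn] = _draw(rng, em.syn_tau, int(syn.sum()))
    phi[syn] = _draw(rng, em.syn_phi, int(syn.sum()))
    tau_class[syn] = phi_class[syn] = "synonymous"

    non = vclass == "nonsense"
    early_t = non & (pos <= em.trafficking_boundary)
    late_t = non & ~ (pos <= em.trafficking_boundary)
    tau[early_t] = _draw(rng, em.nonsense_early_tau, int(early_t.sum()))
    tau[late_t] = _draw(rng, em.nonsense_late_tau, int(late_t.sum()))
    tau_class[early_t], tau_class[late_t] = "loss", "normal"
    early_f = non & (pos <= em.functional_boundary)
    late_f = non & ~ (pos <= em.functional_boundary)
    phi[early_f] = _draw(rng, em.nonsense_early_phi, int(early_f.sum()))
    phi[late_f] = _draw(rng, em.nonsense_late_phi, int(late_f.sum()))
    phi_class[early_f], phi_class[late_f] = "loss", "normal"

    mis = vclass == "missense"
    tau_class[mis], tau[mis] = _draw_mixture(rng, em.missense_tau_mix, int(mis.sum()))
    phi_class[mis], phi[mis] = _draw_mixture(rng, em.missense_phi_mix, int(mis.sum()))
    # couple the two latents: most loss-of-surface variants cannot function
    if (
        em.p_phi_loss_given_tau_loss > 0
        and {"loss", "partial"} <= set(em.missense_phi_mix)
    ):
        coupled = mis & (tau_class == "loss")
        to_loss = coupled & (rng.random(n) < em.p_phi_loss_given_tau_loss)
        to_partial = coupled & ~to_loss
        phi[to_loss] = _draw(rng, em.missense_phi_mix["loss"][1:], int(to_loss.sum()))
        phi[to_partial] = _draw(
            rng, em.missense_phi_mix["partial"][1:], int(to_partial.sum())
        )
        phi_class[to_loss], phi_class[to_partial] = "loss", "partial"

    # start-codon destruction: residue-1 non-synonymous variants are null
    start = (pos == 1) & ~syn
    tau[start] = _draw(rng, em.nonsense_early_tau, int(start.sum()))
    phi[start] = _draw(rng, em.nonsense_early_phi, int(start.sum()))
    tau_class[start] = phi_class[start] = "loss"

    truth = pd.DataFrame(
        {
            "position": pos,
            "ref_aa": outcomes["ref_aa"].to_numpy(),
            "alt_aa": outcomes["alt_aa"].to_numpy(),
            "vclass": vclass,
            "tau": tau,
            "phi": phi,
            "tau_class": tau_class,
            "phi_class": phi_class,
        },
        index=pd.Index(outcomes["name"], name="name"),
    )
    truth.attrs["cds"] = ref.cds

    # zero-truncated negative binomial barcode counts, mean ~= n_barcodes_mean
    r = cfg.barcode_dispersion
    p = r / (r + cfg.n_barcodes_mean)
    n_bc = rng.negative_binomial(r, p, size=n)
    while (n_bc == 0).any():
        zero = n_bc == 0
        n_bc[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    barcodes = _random_barcodes(int(n_bc.sum()), cfg.barcode_length, rng)
    barcode_map = pd.DataFrame(
        {"variant": np.repeat(truth.index.to_numpy(), n_bc)},
        index=pd.Index(barcodes, name="barcode"),
    )
    return barcode_map, truth


def _sample_columns(cfg: SimConfig, role: str, indices) -> list[str]:
    return [
        f"rep{r}:{role}{i}"
        for r in range(1, cfg.n_replicates + 1)
        for i in indices
    ]


def simulate_sortseq(
    barcode_map: pd.DataFrame, truth: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Counts per barcode in each of 4 sorted bins, per replicate.

    Per replicate: cells are allotted to barcodes multinomially (with a
    lognormal clonal-abundance jitter), each cell's fluorescence is
    ``(tau + background) * exp(sd * N(0,1))``, bins split the pooled
    cells at empirical quartiles, and each bin pool is sequenced
    multinomially to ``reads_per_sample`` reads.
    """
    rng = cfg.rng(1)
    tau = truth.loc[barcode_map["variant"], "tau"].to_numpy()
    n_bc = len(barcode_map)
    cols: dict[str, np.ndarray] = {}
    for rep in range(1, cfg.n_replicates + 1):
        abund = np.exp(rng.normal(0.0, cfg.abundance_sd, size=n_bc))
        cells = rng.multinomial(cfg.cells_per_replicate, abund / abund.sum())
        fluor = (np.repeat(tau, cells) + cfg.background_fluorescence) * np.exp(
            rng.normal(0.0, cfg.fluorescence_sd, size=int(cells.sum()))
        )
        edges = np.quantile(fluor, [0.25, 0.5, 0.75])
        bin_id = np.searchsorted(edges, fluor, side="left")
        owner = np.repeat(np.arange(n_bc), cells)
        per_bin = np.bincount(owner * 4 + bin_id, minlength=n_bc * 4).reshape(n_bc, 4)
        for b in range(4):
            pool = per_bin[:, b].astype(float)
            reads = rng.multinomial(cfg.reads_per_sample, pool / pool.sum())
            cols[f"rep{rep}:bin{b + 1}"] = reads
    return pd.DataFrame(cols, index=barcode_map.index)


def simulate_depletion(
    barcode_map: pd.DataFrame, truth: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Counts per barcode at each sampled day, per replicate.

    Barcode frequency at day ``t`` is proportional to
    ``f0 * exp(-growth_coupling * phi * t)``: active variants deplete,
    inactive ones persist.  Each day's sample is sequenced multinomially
    to ``reads_per_sample`` reads.
    """
    rng = cfg.rng(2)
    phi = truth.loc[barcode_map["variant"], "phi"].to_numpy()
    n_bc = len(barcode_map)
    cols: dict[str, np.ndarray] = {}
    for rep in range(1, cfg.n_replicates + 1):
        f0 = np.exp(rng.normal(0.0, cfg.abundance_sd, size=n_bc))
        for day in cfg.days:
            w = f0 * np.exp(-cfg.growth_coupling * phi * day)
            cols[f"rep{rep}:day{day}"] = rng.multinomial(
                cfg.reads_per_sample, w / w.sum()
            )
    return pd.DataFrame(cols, index=barcode_map.index)


def simulate_competition(
    phi_a: float = 1.0,
    phi_b: float = 0.0,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Two-genotype 1:1 competition preset (e.g. WT vs empty vector).

    Returns genotype A's share of reads at each day, per replicate —
    the simulated analogue of the flow-cytometry validation of the
    depletion assay.
    """
    cfg = cfg or SimConfig(protein_length=2, reads_per_sample=100_000, abundance_sd=0.0)
    bc_map = pd.DataFrame(
        {"variant": ["A", "B"]}, index=pd.Index(["A" * 18, "C" * 18], name="barcode")
    )
    truth = pd.DataFrame(
        {"phi": [phi_a, phi_b], "tau": [1.0, 1.0]}, index=pd.Index(["A", "B"], name="name")
    )
    counts = simulate_depletion(bc_map, truth, cfg)
    share = counts.loc["A" * 18] / counts.sum(axis=0)
    out = share.rename("share_a").to_frame()
    out[["replicate", "day"]] = [
        (int(c.split(":")[0][3:]), int(c.split(":day")[1])) for c in out.index
    ]
    return out.reset_index(drop=True)
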