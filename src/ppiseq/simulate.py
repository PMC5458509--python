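"""Generative model of the pooled double-barcode growth assay.

One simulated culture follows the experimental protocol: a pool of
double-barcoded lineages grows deterministically and exponentially for
``generations_per_cycle`` doublings, is sampled for sequencing, and is then
bottlenecked by a 1:8 dilution drawn multinomially from the grown
frequencies.  Sequencing draws a fixed read depth multinomially from the
pool frequencies; a fraction ``chimera_rate`` of reads re-pair their two
barcode halves at random (proportionally to the half marginals), emulating
PCR chimeras.  The simulator keeps a ledger of every chimeric read that
lands outside the designed library, doubles as the test-fixture generator,
and can emit synthetic FASTQ that round-trips through
:mod:`ppiseq.barcode_io`.

Default configuration mirrors the real assay: 10 x 10 genotypes (one
control half each) x 25 barcode pairs = 2,500 lineages, sampled at
generations 0/3/6/9/12, ~67 reads per barcode per time point, 1:8
bottlenecks of ~1.3e6 cells, chimera rate 0.2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping
import warnings

import numpy as np
import pandas as pd

from .barcode_io import (
    BARCODE_LENGTH,
    BARCODE1_RE,
    BARCODE2_RE,
    AmpliconLayout,
    DoubleBarcodeLibrary,
    SampleInfo,
)
from . import io as _io

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one simulated pooled growth experiment."""

    n_bait: int = 10
    n_prey: int = 10
    barcodes_per_bait: int = 5
    barcodes_per_prey: int = 5
    #: genotype-pair fitness map, (bait index, prey index) -> s per
    #: generation; missing pairs default to 0.  Bait/prey index 0 is the
    #: reporter-negative control half.
    fitness_map: Mapping[tuple[int, int], float] = field(default_factory=dict)
    bottleneck_size: int = 1_300_000
    dilution_factor: int = 8
    generations_per_cycle: int = 3
    n_cycles: int = 4
    reads_per_barcode: float = 67.0
    chimera_rate: float = 0.002
    #: fraction of the bait-half x prey-half cross actually constructed;
    #: < 1 leaves off-target landing space for chimeras.
    library_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bait, self.n_prey, self.barcodes_per_bait, self.barcodes_per_prey) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.chimera_rate < 1.0:
            raise ValueError("chimera_rate must be in [0, 1)")
        if not 0.0 < self.library_fraction <= 1.0:
            raise ValueError("library_fraction must be in (0, 1]")
        if self.dilution_factor != 2**self.generations_per_cycle:
            warnings.warn(
                "dilution_factor is not 2**generations_per_cycle; "
                "generation numbering assumes regrowth to saturation",
                stacklevel=2,
            )

    @property
    def n_lineages_full(self) -> int:
        return (
            self.n_bait * self.barcodes_per_bait * self.n_prey * self.barcodes_per_prey
        )

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.generations_per_cycle

    @property
    def read_depth(self) -> int:
        return int(round(self.reads_per_barcode * self.n_lineages_full * self.library_fraction))


def default_experiment_config(seed: int = 0) -> SimConfig:
    """Experiment-scale defaults: 2,500 lineages, 5 time points, 67x depth.

    True genotype fitnesses span the observed range 0 to ~0.4: the 81
    non-control genotype pairs are assigned evenly spaced values on
    [0, 0.4]; pairs with a control half carry no reconstituted reporter
    and get s = 0.
    """
    cfg = SimConfig(seed=seed)
    values = np.linspace(0.0, 0.4, (cfg.n_bait - 1) * (cfg.n_prey - 1))
    fmap: dict[tuple[int, int], float] = {}
    k = 0
    for i in range(1, cfg.n_bait):
        for j in range(1, cfg.n_prey):
            fmap[(i, j)] = float(values[k])
            k += 1
    cfg.fitness_map = fmap
    return cfg


def _random_barcode(rng: np.random.Generator, flank5: str, flank3: str) -> str:
    """A structurally valid 38-bp barcode: flank N{4..7} AA N TT N flank."""
    while True:
        lens = rng.integers(4, 8, size=4)
        if lens.sum() == BARCODE_LENGTH - len(flank5) - len(flank3) - 6:
            break
    segs = ["".join(rng.choice(_BASES, size=n)) for n in lens]
    return f"{flank5}{segs[0]}AA{segs[1]}AA{segs[2]}TT{segs[3]}{flank3}"


def generate_barcodes(n: int, which: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct pattern-conforming barcodes for position 1 or 2."""
    flanks = ("TACC", "ATAA") if which == 1 else ("TTAT", "GGTA")
    pattern = BARCODE1_RE if which == 1 else BARCODE2_RE
    out: list[str] = []
    seen = set()
    while len(out) < n:
        bc = _random_barcode(rng, *flanks)
        if bc in seen or not pattern.search(bc):
            continue
        seen.add(bc)
        out.append(bc)
    return out


@dataclass
class SimResult:
    """Ground truth and observables of one simulated culture."""

    config: SimConfig
    #: designed lineages: entry_id, barcode1, barcode2, bait, prey,
    #: is_control, bait_idx, prey_idx, b1_idx, b2_idx, true_fitness
    library_table: pd.DataFrame
    #: bait-half and prey-half barcode sequences, indexed by half id
    bait_barcodes: list[str]
    prey_barcodes: list[str]
    cells: np.ndarray  # lineages x (n_cycles + 1), post-bottleneck
    reads_true: np.ndarray  # lineages x time points, chimera-free
    reads_observed: np.ndarray  # lineages x time points, chimera-inflated
    off_target: pd.DataFrame  # sample_idx, b1_idx, b2_idx, count
    generations: np.ndarray

    @property
    def true_fitness(self) -> np.ndarray:
        return self.library_table["true_fitness"].to_numpy()

    @property
    def chimeric_reads(self) -> np.ndarray:
        """Chimeric reads per time point (on- plus off-library landings)."""
        return self._chimeras_per_sample

    def to_library(self) -> DoubleBarcodeLibrary:
        cols = ["entry_id", "barcode1", "barcode2", "bait", "prey", "is_control"]
        return DoubleBarcodeLibrary(self.library_table[cols].copy())


def _build_library(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, list[str], list[str]]:
    n_b1 = cfg.n_bait * cfg.barcodes_per_bait
    n_b2 = cfg.n_prey * cfg.barcodes_per_prey
    bait_bcs = generate_barcodes(n_b1, 1, rng)
    prey_bcs = generate_barcodes(n_b2, 2, rng)
    rows = []
    for b1 in range(n_b1):
        bait_idx = b1 // cfg.barcodes_per_bait
        bait = "ctrl" if bait_idx == 0 else f"Bait{bait_idx:02d}"
        for b2 in range(n_b2):
            prey_idx = b2 // cfg.barcodes_per_prey
            prey = "ctrl" if prey_idx == 0 else f"Prey{prey_idx:02d}"
            s = 0.0 if 0 in (bait_idx, prey_idx) else cfg.fitness_map.get((bait_idx, prey_idx), 0.0)
            rows.append(
                (
                    f"{bait}.{b1 % cfg.barcodes_per_bait}|{prey}.{b2 % cfg.barcodes_per_prey}",
                    bait_bcs[b1],
                    prey_bcs[b2],
                    bait,
                    prey,
                    bait_idx == 0 and prey_idx == 0,
                    bait_idx,
                    prey_idx,
                    b1,
                    b2,
                    s,
                )
            )
    lib = pd.DataFrame(
        rows,
        columns=[
            "entry_id", "barcode1", "barcode2", "bait", "prey", "is_control",
            "bait_idx", "prey_idx", "b1_idx", "b2_idx", "true_fitness",
        ],
    )
    if cfg.library_fraction < 1.0:
        keep = rng.random(len(lib)) < cfg.library_fraction
        keep[0] = True  # never empty
        lib = lib.loc[keep].reset_index(drop=True)
    return lib, bait_bcs, prey_bcs


def simulate_pool(
    config: SimConfig,
    seed: int | None = None,
    sampling: str = "multinomial",
) -> SimResult:
    """Simulate one pooled growth culture.

    ``sampling="expected"`` replaces every stochastic draw (bottleneck,
    sequencing, chimerism) with its expectation, yielding noiseless
    fractional counts that follow the model equations exactly.
    """
    if sampling not in ("multinomial", "expected"):
        raise ValueError("sampling must be 'multinomial' or 'expected'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lib, bait_bcs, prey_bcs = _build_library(config, rng)
    L = len(lib)
    s = lib["true_fitness"].to_numpy()
    g = config.generations_per_cycle
    N = config.bottleneck_size
    depth = config.read_depth
    if N < L:
        warnings.warn("bottleneck smaller than lineage count; heavy extinction", stacklevel=2)

    n_b2 = config.n_prey * config.barcodes_per_prey
    grid_entry = np.full(
        (config.n_bait * config.barcodes_per_bait) * n_b2, -1, dtype=np.int64
    )
    grid_entry[lib["b1_idx"].to_numpy() * n_b2 + lib["b2_idx"].to_numpy()] = np.arange(L)

    T = config.n_cycles + 1
    cells = np.zeros((L, T))
    reads_true = np.zeros((L, T))
    reads_obs = np.zeros((L, T))
    chim_per_sample = np.zeros(T)
    off_rows: list[tuple[int, int, int, int]] = []

    if sampling == "multinomial":
        cells[:, 0] = rng.multinomial(N, np.full(L, 1.0 / L))
    else:
        cells[:, 0] = N / L

    for k in range(T):
        freq = cells[:, k] / cells[:, k].sum()
        # sequencing sample at this time point
        if sampling == "multinomial":
            n_ch = rng.binomial(depth, config.chimera_rate)
            reads_true[:, k] = rng.multinomial(depth - n_ch, freq)
            if n_ch:
                p1 = np.bincount(
                    lib["b1_idx"].to_numpy(), weights=freq,
                    minlength=config.n_bait * config.barcodes_per_bait,
                )
                p2 = np.bincount(lib["b2_idx"].to_numpy(), weights=freq, minlength=n_b2)
                c1 = rng.choice(len(p1), size=n_ch, p=p1 / p1.sum())
                c2 = rng.choice(len(p2), size=n_ch, p=p2 / p2.sum())
                flat = np.bincount(c1 * n_b2 + c2, minlength=len(grid_entry))
                hit = grid_entry >= 0
                on = np.zeros(L)
                on[grid_entry[hit]] = flat[hit]
                reads_obs[:, k] = reads_true[:, k] + on
                off_cells = np.flatnonzero((flat > 0) & ~hit)
                for cell in off_cells:
                    off_rows.append((k, cell // n_b2, cell % n_b2, int(flat[cell])))
            else:
                reads_obs[:, k] = reads_true[:, k]
            chim_per_sample[k] = n_ch
        else:
            reads_true[:, k] = depth * freq * (1 - config.chimera_rate)
            p1 = np.bincount(
                lib["b1_idx"].to_numpy(), weights=freq,
                minlength=config.n_bait * config.barcodes_per_bait,
            )
            p2 = np.bincount(lib["b2_idx"].to_numpy(), weights=freq, minlength=n_b2)
            on = p1[lib["b1_idx"]] * p2[lib["b2_idx"]]
            reads_obs[:, k] = reads_true[:, k] + depth * config.chimera_rate * on
            chim_per_sample[k] = depth * config.chimera_rate
        # growth + bottleneck into next cycle
        if k < T - 1:
            # neutral lineages double once per generation; fitness s is the
            # per-generation log-frequency advantage, matching the
            # parameterization inferred by ppiseq.fitness
            grown = freq * np.exp(g * (np.log(2.0) + s))
            grown /= grown.sum()
            if sampling == "multinomial":
                cells[:, k + 1] = rng.multinomial(N, grown)
            else:
                cells[:, k + 1] = N * grown

    off = pd.DataFrame(off_rows, columns=["sample_idx", "b1_idx", "b2_idx", "count"])
    result = SimResult(
        config, lib, bait_bcs, prey_bcs, cells, reads_true, reads_obs,
        off, config.generations.copy(),
    )
    result._chimeras_per_sample = chim_per_sample
    return result


def off_target_frame(result: SimResult) -> pd.DataFrame:
    """Off-target ledger as barcode sequences (barcode1, barcode2, count)."""
    off = result.off_target
    return pd.DataFrame(
        {
            "sample_idx": off["sample_idx"],
            "barcode1": [result.bait_barcodes[i] for i in off["b1_idx"]],
            "barcode2": [result.prey_barcodes[j] for j in off["b2_idx"]],
            "count": off["count"],
        }
    )


def to_trajectories(
    result: SimResult,
    condition: str = "DMSO",
    mtx: bool = True,
    replicate: int = 1,
) -> pd.DataFrame:
    """Observed read matrix in the flat trajectory schema."""
    lib = result.library_table
    df = pd.DataFrame(
        {
            "PPI_pair": lib["bait"] + ":" + lib["prey"],
            "barcode_pair": lib["entry_id"],
            "Bait": lib["bait"],
            "Prey": lib["prey"],
            "Condition": condition,
            "Methotrexate_selection": mtx,
            "Replicate": replicate,
        }
    )
    for k, gen in enumerate(result.generations):
        df[_io.reads_column(int(gen))] = result.reads_observed[:, k].astype(np.int64)
    return df


def simulate_experiment(
    config: SimConfig,
    conditions: Mapping[str, Mapping[tuple[int, int], float]] | None = None,
    n_replicates: int = 3,
    mtx: bool = True,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate cultures (optionally across conditions).

    ``conditions`` maps a condition label to its fitness map; ``None``
    simulates the config's own map under label ``DMSO``.  Lineage
    identities (entry ids, genotype pairs, true fitnesses) are shared
    across cultures; replicates differ in growth and sequencing noise.
    Returns (trajectory table, truth table per lineage x condition).
    """
    if conditions is None:
        conditions = {"DMSO": dict(config.fitness_map)}
    base_seed = config.seed if seed is None else seed
    frames = []
    truths = []
    for c_idx, (cond, fmap) in enumerate(conditions.items()):
        cfg = replace(config, fitness_map=dict(fmap))
        for rep in range(1, n_replicates + 1):
            res = simulate_pool(cfg, seed=base_seed + 1000 * c_idx + rep)
            frames.append(to_trajectories(res, condition=cond, mtx=mtx, replicate=rep))
        truth = res.library_table[["entry_id", "bait", "prey", "is_control", "true_fitness"]].copy()
        truth["Condition"] = cond
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True)


def _tag(i: int, length: int = 6) -> str:
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(length))


def sample_tags(result: SimResult, condition: str = "DMSO", mtx: bool = True, replicate: int = 1):
    """Deterministic (tag pair -> sample id, sample id -> info) maps."""
    tag_map: dict[tuple[str, str], str] = {}
    info: dict[str, SampleInfo] = {}
    for k, gen in enumerate(result.generations):
        sid = f"{condition}{'+' if mtx else '-'}MTX_r{replicate}_g{int(gen)}"
        tag_map[(_tag(2 * k + 1), _tag(2 * k + 2))] = sid
        info[sid] = SampleInfo(condition, mtx, replicate, int(gen))
    return tag_map, info


def emit_fastq(
    result: SimResult,
    directory,
    layout: AmpliconLayout | None = None,
    quality: int = 40,
    condition: str = "DMSO",
    mtx: bool = True,
    replicate: int = 1,
    seed: int = 0,
) -> list[Path]:
    """Write one FASTQ per time point embedding the simulated barcodes.

    Chimeric off-library reads embed their re-paired halves.  With
    error-free qualities the files round-trip through
    :func:`ppiseq.barcode_io.demultiplex_and_tabulate` to
    ``result.reads_observed`` exactly.
    """
    layout = layout or AmpliconLayout()
    rng = np.random.default_rng(seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag_map, info = sample_tags(result, condition, mtx, replicate)
    tag_by_k = list(tag_map)
    lib = result.library_table
    qline_cache: dict[int, str] = {}
    paths = []
    counts_obs = np.rint(result.reads_observed).astype(np.int64)
    for k, gen in enumerate(result.generations):
        sid = list(info)[k]
        tag1, tag2 = tag_by_k[k]
        seqs: list[str] = []
        for row, n in zip(lib.itertuples(index=False), counts_obs[:, k]):
            if n > 0:
                seqs.extend([f"{tag1}{row.barcode1}{layout.spacer}{row.barcode2}{tag2}"] * int(n))
        off_k = result.off_target[result.off_target["sample_idx"] == k]
        for row in off_k.itertuples(index=False):
            seq = (
                f"{tag1}{result.bait_barcodes[row.b1_idx]}{layout.spacer}"
                f"{result.prey_barcodes[row.b2_idx]}{tag2}"
            )
            seqs.extend([seq] * int(row.count))
        order = rng.permutation(len(seqs))
        path = directory / f"{sid}.fastq"
        with open(path, "w") as fh:
            for i, idx in enumerate(order):
                seq = seqs[idx]
                qline = qline_cache.setdefault(len(seq), chr(quality + 33) * len(seq))
                fh.write(f"@{sid}:{i}\n{seq}\n+\n{qline}\n")
        paths.append(path)
    return paths
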