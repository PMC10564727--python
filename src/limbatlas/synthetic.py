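"""Multi-species synthetic scRNA-seq and spatial data with known ground truth.

The generator emulates the data regimes the pipeline is built for: a panel of
developing-limb datasets from several species sharing a core of one-to-one
orthologous symbols, one species carrying a private (goblet-like) cell type,
one pseudo-tetraploid species whose genes appear as L/S homeolog row pairs, a
cell-cycle confound, an AER expression program planted in ectodermal
signaling cells, a regeneration time course whose wound epithelium (AEC)
re-uses only part of that program, and a Visium-style section whose spots sum
single-cell transcriptomes from contiguous tissue domains.

Counts follow a negative-binomial (gamma-Poisson) model: each cell's expected
expression is its type's mean profile, modulated in log space by planted
program and cycle shifts, then rescaled so expected library size equals
``depth_mean`` times a log-normal per-cell size factor.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import io as _io

__all__ = [
    "SynthConfig",
    "generate_development_panel",
    "generate_regeneration_series",
    "generate_spatial_section",
    "generate_planted_programs",
    "make_orthology",
    "save_panel",
]

# lineage of each synthetic cell type
_LINEAGE = {
    "AER": "ectoderm",
    "AEC": "ectoderm",
    "ectoderm": "ectoderm",
    "goblet": "ectoderm",
    "mesoderm": "mesoderm",
    "CT": "mesoderm",
    "muscle": "mesoderm",
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic multi-species panel.

    Effect sizes (``aer_effect``, ``marker_effect``, ``cycle_strength``) are
    natural-log shifts of the expected expression of the affected genes.
    """

    n_species: int = 5
    cells_per_dataset: int = 800
    n_genes: int = 1200  # genes per dataset (shared core + own private symbols)
    shared_types: tuple[str, ...] = ("AER", "ectoderm", "mesoderm", "CT", "muscle")
    private_types: dict[int, str] = field(default_factory=lambda: {0: "goblet"})
    aer_program_genes: int = 100
    aer_effect: float = 2.0
    marker_genes_per_type: int = 40
    marker_effect: float = 2.0
    homeolog_species: int = 1
    n_homeolog_genes: int = 100
    homeolog_split: float = 0.7  # fraction of the gene mean assigned to the L copy
    n_cycle_genes: int = 50
    cycle_strength: float = 2.0
    cycle_base_shift: float = -2.0  # cycle genes are lowly expressed at baseline
    cycling_fraction: float = 0.2
    n_private_genes: int = 50
    # regeneration mode
    n_timepoints: int = 3
    ct_program_fraction: float = 0.3
    ct_program_size: int = 60
    aec_overlap: float = 0.6
    # spatial mode
    grid_shape: tuple[int, int] = (20, 20)
    cells_per_spot: int = 10
    negative_control_species: int | None = None
    nb_dispersion: float = 0.3
    depth_mean: float = 3000.0
    depth_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cycling_fraction", "ct_program_fraction", "aec_overlap",
                     "homeolog_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes < self.aer_program_genes + self.n_cycle_genes:
            raise ValueError(
                "n_genes must accommodate the AER program and cycle gene blocks"
            )
        if self.cells_per_dataset < 1:
            raise ValueError("cells_per_dataset must be >= 1")

    # --- gene layout -----------------------------------------------------
    def core_symbols(self) -> list[str]:
        """Shared symbols present in every species, in fixed order."""
        n_core = self.n_genes - self.n_private_genes
        names = [f"PRG{i:03d}" for i in range(self.aer_program_genes)]
        names += [f"CYC{i:03d}" for i in range(self.n_cycle_genes)]
        marker_types = [t for t in self.shared_types if t != "AER"]
        marker_types += sorted(set(self.private_types.values())) + ["AEC_extra"]
        for t in marker_types:
            names += [f"MK_{t}_{i:02d}" for i in range(self.marker_genes_per_type)]
        n_bg = n_core - len(names)
        if n_bg < self.n_homeolog_genes:
            raise ValueError("n_genes too small for the configured gene blocks")
        names += [f"BG{i:04d}" for i in range(n_bg)]
        return names

    def program_symbols(self) -> list[str]:
        return [f"PRG{i:03d}" for i in range(self.aer_program_genes)]

    def cycle_symbols(self) -> list[str]:
        return [f"CYC{i:03d}" for i in range(self.n_cycle_genes)]

    def ct_program_symbols(self) -> list[str]:
        """Program subset planted in connective-tissue cells (regeneration).

        Drawn from the AEC-shared (epithelial) portion of the AER program:
        the planted CT cells display the part of the program the wound
        epithelium also runs, so by default the subset coincides with the
        AEC overlap genes.
        """
        n = min(self.ct_program_size, self.aer_program_genes)
        return self.program_symbols()[:n]

    def aec_program_symbols(self) -> list[str]:
        n = round(self.aec_overlap * self.aer_program_genes)
        return self.program_symbols()[:n]

    def private_symbols(self, species: int) -> list[str]:
        return [f"PV{species}_{i:03d}" for i in range(self.n_private_genes)]

    def homeolog_symbols(self) -> list[str]:
        core = self.core_symbols()
        return core[len(core) - self.n_homeolog_genes:]

    def species_name(self, s: int) -> str:
        return f"sp{s}"

    # --- serialization ---------------------------------------------------
    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["shared_types"] = list(self.shared_types)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["shared_types"] = tuple(d["shared_types"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["private_types"] = {int(k): v for k, v in d["private_types"].items()}
        return cls(**d)


def make_orthology(config: SynthConfig) -> pd.DataFrame:
    """Orthology table covering every source gene id the panel emits."""
    rows = []
    homeologs = set(config.homeolog_symbols())
    for s in range(config.n_species):
        sp = config.species_name(s)
        for sym in config.core_symbols() + config.private_symbols(s):
            if s == config.homeolog_species and sym in homeologs:
                rows.append((f"{sym}.L", sp, sym, "L"))
                rows.append((f"{sym}.S", sp, sym, "S"))
            else:
                rows.append((sym, sp, sym, "t1"))
    return pd.DataFrame(
        rows, columns=["source_gene_id", "species", "shared_symbol", "group_tag"]
    )


# ---------------------------------------------------------------------------
# mean-profile machinery


def _base_log_means(config: SynthConfig, symbols: list[str]) -> np.ndarray:
    """Baseline log-mean per symbol, shared across types and species.

    Derived from the config seed only, so every dataset of a panel sees the
    same baseline for a given symbol.
    """
    rng = np.random.default_rng(config.seed + 10_007)
    base = rng.normal(0.0, 1.0, size=len(symbols))
    # cycle genes sit low at baseline so that their induction reshapes only
    # a small share of the library (keeps the confound realistic)
    for i, g in enumerate(symbols):
        if g.startswith("CYC"):
            base[i] += config.cycle_base_shift
    return base


def _type_log_profile(config: SynthConfig, symbols: list[str], base: np.ndarray,
                      cell_type: str) -> np.ndarray:
    """Type mean profile in log space: baseline plus marker/program shifts."""
    prof = base.copy()
    idx = {g: i for i, g in enumerate(symbols)}

    def bump(genes, eff):
        for g in genes:
            j = idx.get(g)
            if j is not None:
                prof[j] += eff

    if cell_type == "AER":
        bump(config.program_symbols(), config.aer_effect)
    elif cell_type == "AEC":
        bump(config.aec_program_symbols(), config.aer_effect)
        bump([f"MK_AEC_extra_{i:02d}" for i in range(config.marker_genes_per_type)],
             config.marker_effect)
    else:
        bump([f"MK_{cell_type}_{i:02d}" for i in range(config.marker_genes_per_type)],
             config.marker_effect)
    return prof


def _sample_counts(config: SynthConfig, mu: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts via a gamma-Poisson mixture, preserving mu."""
    d = config.nb_dispersion
    if d <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / d, scale=mu * d)
    return rng.poisson(lam)


def _build_dataset(
    config: SynthConfig,
    symbols: list[str],
    type_of_cell: list[str],
    dataset_id: str,
    species: str,
    rng: np.random.Generator,
    cycling: np.ndarray | None = None,
    extra_shift: dict[int, tuple[list[str], float]] | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Assemble one dataset: mean matrix -> depth scaling -> NB sampling.

    ``extra_shift`` maps cell index -> (gene symbols, log shift) for planted
    per-cell programs (the regenerating-CT program).
    """
    n_cells, n_genes = len(type_of_cell), len(symbols)
    base = _base_log_means(config, symbols)
    profiles = {t: _type_log_profile(config, symbols, base, t)
                for t in sorted(set(type_of_cell))}
    log_mu = np.stack([profiles[t] for t in type_of_cell])

    if cycling is None:
        cycling = np.zeros(n_cells, dtype=bool)
    cyc_idx = [i for i, g in enumerate(symbols) if g.startswith("CYC")]
    if cycling.any() and cyc_idx:
        log_mu[np.ix_(np.flatnonzero(cycling), cyc_idx)] += config.cycle_strength

    idx = {g: i for i, g in enumerate(symbols)}
    if extra_shift:
        for ci, (genes, eff) in extra_shift.items():
            cols = [idx[g] for g in genes if g in idx]
            log_mu[ci, cols] += eff

    mu = np.exp(log_mu)
    size = np.exp(rng.normal(-config.depth_sigma**2 / 2, config.depth_sigma, n_cells))
    mu *= (config.depth_mean * size / mu.sum(axis=1))[:, None]

    counts = _sample_counts(config, mu, rng)
    cell_ids = [f"{dataset_id}_c{i:04d}" for i in range(n_cells)]
    carries = np.array([bool(extra_shift and i in extra_shift)
                        for i in range(n_cells)])
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "species": species,
            "dataset_id": dataset_id,
            "true_type": type_of_cell,
            "lineage": [_LINEAGE.get(t, "other") for t in type_of_cell],
            "cycling": cycling,
            "carries_program": carries,
        }
    )
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell")),
        var=pd.DataFrame(index=pd.Index(symbols, name="gene")),
        layers={"mean": mu},
    )
    adata.obs["dataset"] = dataset_id
    adata.obs["species"] = species
    return adata, truth


def _split_homeologs(config: SynthConfig, adata: ad.AnnData,
                     rng: np.random.Generator) -> ad.AnnData:
    """Replace homeolog symbols by SYM.L / SYM.S rows splitting the mean."""
    homeologs = set(config.homeolog_symbols())
    p = config.homeolog_split
    mu = adata.layers["mean"]
    new_cols, new_names, new_mu = [], [], []
    for j, g in enumerate(adata.var_names):
        if g in homeologs:
            mu_l, mu_s = mu[:, j] * p, mu[:, j] * (1 - p)
            new_cols += [_sample_counts(config, mu_l, rng),
                         _sample_counts(config, mu_s, rng)]
            new_mu += [mu_l, mu_s]
            new_names += [f"{g}.L", f"{g}.S"]
        else:
            new_cols.append(np.asarray(adata.X[:, j]).ravel())
            new_mu.append(mu[:, j])
            new_names.append(g)
    out = ad.AnnData(
        X=np.column_stack(new_cols),
        obs=adata.obs.copy(),
        var=pd.DataFrame(index=pd.Index(new_names, name="gene")),
        layers={"mean": np.column_stack(new_mu)},
    )
    return out


def _allocate_types(config: SynthConfig, types: list[str]) -> list[str]:
    """Assign cells_per_dataset cells to types in near-equal blocks."""
    n, k = config.cells_per_dataset, len(types)
    if n < k:
        raise ValueError(
            f"cells_per_dataset={n} is smaller than the {k} declared types "
            f"({types}); each type needs at least one cell"
        )
    counts = [n // k + (1 if i < n % k else 0) for i in range(k)]
    out: list[str] = []
    for t, c in zip(types, counts):
        out += [t] * c
    return out


# ---------------------------------------------------------------------------
# public generators


def generate_development_panel(
    config: SynthConfig,
) -> list[tuple[ad.AnnData, pd.DataFrame]]:
    """One developing-limb dataset per species, with planted ground truth.

    Every dataset (except a configured negative control) contains AER cells
    over-expressing the planted program; the homeolog species emits L/S row
    pairs; each species' matrix carries its own private symbols; a species
    may carry a private cell type (the goblet analog).
    """
    rng = np.random.default_rng(config.seed)
    panel = []
    for s in range(config.n_species):
        types = list(config.shared_types)
        if config.negative_control_species == s:
            types = [t for t in types if t != "AER"]
        if s in config.private_types:
            types.append(config.private_types[s])
        symbols = config.core_symbols() + config.private_symbols(s)
        type_of_cell = _allocate_types(config, types)
        cycling = rng.random(config.cells_per_dataset) < config.cycling_fraction
        adata, truth = _build_dataset(
            config, symbols, type_of_cell, dataset_id=f"dev_sp{s}",
            species=config.species_name(s), rng=rng, cycling=cycling,
        )
        if s == config.homeolog_species:
            adata = _split_homeologs(config, adata, rng)
        panel.append((adata, truth))
    return panel


def generate_regeneration_series(
    config: SynthConfig,
) -> list[tuple[ad.AnnData, pd.DataFrame]]:
    """Regenerating-limb time course for the focal species (symbol space).

    Each timepoint contains AEC cells expressing a fraction ``aec_overlap``
    of the AER program (the rest of the program dropped, as when FGF-pathway
    ligands are absent from the wound epithelium), connective tissue of which
    exactly ``round(ct_program_fraction * n_CT)`` cells additionally carry
    the CT-planted program subset, plus ectoderm and mesoderm.
    """
    rng = np.random.default_rng(config.seed + 1)
    symbols = config.core_symbols()
    out = []
    for t in range(config.n_timepoints):
        types = ["AEC", "CT", "ectoderm", "mesoderm"]
        type_of_cell = _allocate_types(config, types)
        ct_cells = [i for i, ty in enumerate(type_of_cell) if ty == "CT"]
        n_flag = round(config.ct_program_fraction * len(ct_cells))
        flagged = rng.choice(ct_cells, size=n_flag, replace=False) if n_flag else []
        extra = {int(i): (config.ct_program_symbols(), config.aer_effect)
                 for i in flagged}
        cycling = rng.random(config.cells_per_dataset) < config.cycling_fraction
        adata, truth = _build_dataset(
            config, symbols, type_of_cell, dataset_id=f"regen_t{t}",
            species=config.species_name(0), rng=rng, cycling=cycling,
            extra_shift=extra,
        )
        adata.obs["timepoint"] = t
        truth["timepoint"] = t
        out.append((adata, truth))
    return out


def generate_spatial_section(
    config: SynthConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """A Visium-style section of a regenerating limb.

    The grid is split into three contiguous domains along the
    proximo-distal axis: intact connective tissue, blastema (enriched for
    program-carrying CT), and an AEC rim at the distal edge. Each spot's
    counts are the sum of ``cells_per_spot`` synthetic single cells sampled
    from its domain's type mixture.
    """
    rows, cols = config.grid_shape
    if cols < 3 or rows < 1:
        raise ValueError(
            f"grid {rows}x{cols} too small to host three tissue domains"
        )
    rng = np.random.default_rng(config.seed + 2)
    symbols = config.core_symbols()

    # pools of single cells per constituent population
    pool_types = {
        "CT": "CT",
        "CT_prog": "CT",
        "AEC": "AEC",
        "ectoderm": "ectoderm",
    }
    pool_n = 300
    pools: dict[str, np.ndarray] = {}
    for name, ty in pool_types.items():
        extra = None
        if name == "CT_prog":
            extra = {i: (config.ct_program_symbols(), config.aer_effect)
                     for i in range(pool_n)}
        adata, _ = _build_dataset(
            config, symbols, [ty] * pool_n, dataset_id=f"pool_{name}",
            species=config.species_name(0), rng=rng, extra_shift=extra,
        )
        pools[name] = np.asarray(adata.X)

    # domain mixtures: population -> sampling weight
    mixtures = {
        "intact_CT": {"CT": 0.8, "ectoderm": 0.2},
        "blastema": {"CT_prog": 0.6, "CT": 0.3, "ectoderm": 0.1},
        "AEC_rim": {"AEC": 0.7, "CT": 0.3},
    }
    rim_w = max(1, cols // 10)  # distal-edge columns forming the AEC rim
    inner = cols - rim_w
    split = max(1, inner // 2)

    def domain_of(col: int) -> str:
        if col >= inner:
            return "AEC_rim"
        return "intact_CT" if col < split else "blastema"

    spot_counts, records, members = [], [], []
    for r in range(rows):
        for c in range(cols):
            dom = mixtures[domain_of(c)]
            names = list(dom)
            probs = np.array([dom[k] for k in names])
            picks = rng.choice(len(names), size=config.cells_per_spot,
                               p=probs / probs.sum())
            cell_rows = []
            for k in picks:
                i = int(rng.integers(pool_n))
                cell_rows.append(pools[names[k]][i])
                members.append((f"spot_r{r:02d}c{c:02d}", names[k], i))
            spot_counts.append(np.sum(cell_rows, axis=0))
            records.append((f"spot_r{r:02d}c{c:02d}", r, c, domain_of(c)))

    barcodes = [rec[0] for rec in records]
    adata = ad.AnnData(
        X=np.stack(spot_counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="spot")),
        var=pd.DataFrame(index=pd.Index(symbols, name="gene")),
    )
    adata.obs["dataset"] = "visium_section"
    adata.obs["species"] = config.species_name(0)
    positions = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": 1,
            "array_row": [rec[1] for rec in records],
            "array_col": [rec[2] for rec in records],
            "pxl_row_in_fullres": [rec[1] * 100 for rec in records],
            "pxl_col_in_fullres": [rec[2] * 100 for rec in records],
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": barcodes,
            "species": config.species_name(0),
            "dataset_id": "visium_section",
            "true_type": [rec[3] for rec in records],
            "lineage": "spot",
            "cycling": False,
            "carries_program": [rec[3] in ("blastema", "AEC_rim")
                                for rec in records],
        }
    )
    adata.uns["spot_members"] = pd.DataFrame(
        members, columns=["barcode", "pool", "pool_index"]
    )
    adata.uns["pools"] = {k: v for k, v in pools.items()}
    return adata, positions, truth


def generate_planted_programs(
    n_cells: int = 240,
    n_programs: int = 3,
    genes_per_program: int = 30,
    background_usage: tuple[float, float] = (0.05, 0.15),
    nb_dispersion: float = 0.5,
    depth_mean: float = 2000.0,
    seed: int = 0,
) -> tuple[ad.AnnData, list[list[str]]]:
    """Counts whose expectation is an exact nonnegative rank-``n_programs``
    product: disjoint gene spectra times cell usages, plus NB noise.

    Each cell has a dominant program (cells cycle through programs) plus a
    small uniform background usage of the others, so that the planted rank
    is the only low-dimensional structure. Returns the dataset (with a
    ``normalized`` layer) and the gene blocks of each program.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_programs * genes_per_program
    spectra = np.zeros((n_programs, n_genes))
    blocks = []
    for p in range(n_programs):
        cols = range(p * genes_per_program, (p + 1) * genes_per_program)
        spectra[p, list(cols)] = rng.lognormal(0.0, 0.5, genes_per_program)
        blocks.append([f"g{j:03d}" for j in cols])
    usages = rng.uniform(*background_usage, (n_cells, n_programs))
    dominant = np.arange(n_cells) % n_programs
    usages[np.arange(n_cells), dominant] += rng.lognormal(0.0, 0.3, n_cells)
    mu = usages @ spectra
    mu *= depth_mean / mu.sum(axis=1, keepdims=True)
    lam = rng.gamma(1.0 / nb_dispersion, mu * nb_dispersion)
    counts = rng.poisson(lam)
    adata = ad.AnnData(
        X=counts.astype(float),
        obs=pd.DataFrame(index=pd.Index(
            [f"pc{i:04d}" for i in range(n_cells)], name="cell")),
        var=pd.DataFrame(index=pd.Index(
            [f"g{j:03d}" for j in range(n_genes)], name="gene")),
    )
    adata.obs["dataset"] = "planted_programs"
    adata.obs["program"] = dominant
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    adata.layers["normalized"] = np.log1p(counts / totals * 1e4)
    return adata, blocks


def save_panel(
    panel: list[tuple[ad.AnnData, pd.DataFrame]],
    directory: str | os.PathLike,
    config: SynthConfig | None = None,
) -> None:
    """Write each dataset as a 10x MTX bundle plus truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for adata, truth in panel:
        ds = adata.obs["dataset"].iloc[0]
        _io.write_10x_mtx(adata, directory / ds)
        truth.to_csv(directory / ds / "truth.tsv", sep="\t", index=False)
    if config is not None:
        config.to_yaml(directory / "config.yaml")
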