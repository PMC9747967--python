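"""Visium-like dataset simulation with planted ground truth.

The generator lays out a hex grid with depth-ordered layer bands (upper
epidermis at the top through dermis 7 at the bottom), plants sparse
cytokine-positive spots in the epidermis (1–15 UMIs each, uniformly),
co-locates leukocyte marker counts with them, and draws all other genes
from a gamma-Poisson (negative binomial, ``variance = mu + mu²/
dispersion``) model.  Responder genes of a cytokine have their mean
amplified for spots within the planted hex radius of that cytokine's
positive spots; the amplification scales with the local cytokine UMI
load, so clusters capturing more transcripts show a stronger response —
the signal the radius sweep estimates.

No generative model is published for such data; every distributional
choice here is a stand-in whose only job is to make parameter-recovery
tests well-posed.  The "within radius" relation reuses the exact hex
neighbourhood of the clustering module, so the planted radius is
expressed in the unit the estimator measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .annotate import DEFAULT_MARKERS
from .hexcluster import HexCoord, hex_offsets
from .spatial_io import LAYER_VOCAB, SpotDataset

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "simulate_stim_table"]

_BAND_LAYERS = LAYER_VOCAB[:11]  # everything except "excluded"


@dataclass
class SimConfig:
    n_rows: int = 26
    n_cols: int = 28
    #: rows per layer band, top to bottom, aligned with _BAND_LAYERS;
    #: leftover rows extend the last band.
    layer_widths: tuple[int, ...] = (6, 6, 6, 1, 1, 1, 1, 1, 1, 1, 1)
    n_samples: int = 8
    n_genes: int = 80
    n_responder_genes: int = 8
    cytokine_names: tuple[str, ...] = ("IFNG", "IL13", "IL17A")
    cytokine_spot_rate: float = 0.02
    cytokine_umi_range: tuple[int, int] = (1, 15)
    true_radius: dict[str, int] = field(
        default_factory=lambda: {"IFNG": 4, "IL13": 3, "IL17A": 0}
    )
    amplification: float = 3.0
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS
    marker_background_mean: float = 0.05
    #: log-scale sd and smoothing length (grid units) of the spatially
    #: correlated baseline multiplier applied to responder genes only;
    #: emulates patchy cytokine-independent keratinocyte activity.
    responder_field_sd: float = 0.4
    responder_field_scale: float = 2.0
    #: cap on planted cytokine+ spots per sample and cytokine (None = no
    #: cap); with a cap of 1 clusters never merge and parameter-recovery
    #: tests see one clean microenvironment per section.
    max_seeds_per_sample: int | None = None
    #: keep planted seeds this many grid units away from the grid's
    #: column edges and from the epidermal band's row edges, so the
    #: planted action ball is not truncated by the section boundary.
    seed_margin: int = 0
    #: when set, the induced response is a fixed per-transcript budget
    #: spread over the radius-t ball (per-spot mean scaled by
    #: response_budget_spots / ball size) instead of a constant per-spot
    #: boost; emulates dilution of a diffusing signal.
    response_budget_spots: float | None = None
    mt_gene_count: int = 3
    mt_mean: float = 3.0
    housekeeping_gene: str = "GAPDH"
    housekeeping_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cytokine_spot_rate <= 1.0:
            raise ValueError("cytokine_spot_rate must be in [0, 1]")
        lo, hi = self.cytokine_umi_range
        if not (1 <= lo <= hi):
            raise ValueError("cytokine_umi_range must satisfy 1 <= lo <= hi")
        for cyt, r in self.true_radius.items():
            if r < 0:
                raise ValueError(f"true_radius[{cyt}] must be >= 0")
        if self.amplification < 1.0:
            raise ValueError("amplification must be >= 1")
        if min(self.baseline_mean, self.mt_mean, self.housekeeping_mean) <= 0:
            raise ValueError("all means must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if sum(self.layer_widths) > self.n_rows:
            raise ValueError(
                f"grid of {self.n_rows} rows too small for layer widths "
                f"summing to {sum(self.layer_widths)}"
            )
        missing = set(self.cytokine_names) - set(self.true_radius)
        if missing:
            raise ValueError(f"true_radius missing for cytokines: {sorted(missing)}")

    @classmethod
    def recovery_protocol(cls, true_radius: int, seed: int = 0, **overrides) -> "SimConfig":
        """Configuration for radius parameter-recovery runs: many small
        sections, one planted untruncated microenvironment each, so the
        sweep sees independent clean clusters."""
        kw = dict(
            n_samples=40,
            n_rows=26,
            n_cols=28,
            cytokine_spot_rate=0.05,
            max_seeds_per_sample=1,
            seed_margin=4,
            nb_dispersion=2.0,
            amplification=3.0,
            responder_field_sd=0.4,
            true_radius={"IFNG": true_radius, "IL13": true_radius, "IL17A": true_radius},
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Planted structure: where the cytokine spots are, how far they act,
    which genes respond, and the stimulation-table effect sizes."""

    cytokine_spots: dict[str, dict[str, list[tuple[int, int, int]]]]
    true_radius: dict[str, int]
    responder_genes: dict[str, list[str]]
    planted_log2fc: dict[str, dict[str, float]]  # cytokine -> gene -> log2FC

    def to_json(self, path) -> None:
        payload = {
            "cytokine_spots": {
                c: {s: [list(t) for t in v] for s, v in per.items()}
                for c, per in self.cytokine_spots.items()
            },
            "true_radius": self.true_radius,
            "responder_genes": self.responder_genes,
            "planted_log2fc": self.planted_log2fc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _layer_of_row(row: int, cfg: SimConfig) -> str:
    edge = 0
    for width, layer in zip(cfg.layer_widths, _BAND_LAYERS):
        edge += width
        if row < edge:
            return layer
    return _BAND_LAYERS[len(cfg.layer_widths) - 1]


def _responder_field(
    rng: np.random.Generator, cfg: SimConfig, coords: list[HexCoord]
) -> np.ndarray:
    """Per-spot lognormal baseline multiplier with spatial correlation
    (unit mean).  Shared by all responder genes of one sample."""
    if cfg.responder_field_sd <= 0:
        return np.ones(len(coords))
    raw = rng.normal(size=(cfg.n_rows, cfg.n_cols))
    smooth = gaussian_filter(raw, sigma=cfg.responder_field_scale, mode="wrap")
    smooth = smooth / max(smooth.std(), 1e-12) * cfg.responder_field_sd
    mult = np.exp(smooth - cfg.responder_field_sd**2 / 2.0)
    return np.array([mult[r, c] for r, c in coords])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu²/dispersion."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _gene_panel(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    responders = {
        cyt: [f"RESP-{cyt}-{i + 1:02d}" for i in range(cfg.n_responder_genes)]
        for cyt in cfg.cytokine_names
    }
    genes: list[str] = list(cfg.cytokine_names)
    genes += list(cfg.marker_genes)
    for cyt in cfg.cytokine_names:
        genes += responders[cyt]
    genes += [f"MT-SIM{i + 1}" for i in range(cfg.mt_gene_count)]
    genes.append(cfg.housekeeping_gene)
    genes += [f"BGGENE{i + 1:04d}" for i in range(cfg.n_genes)]
    return genes, responders


def simulate_dataset(cfg: SimConfig) -> tuple[SpotDataset, GroundTruth]:
    """Generate a multi-sample hex-grid dataset with known ground truth.

    Reproducible: each sample uses its own RNG stream derived from
    ``cfg.seed`` and the sample index.
    """
    genes, responders = _gene_panel(cfg)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    u_lo, u_hi = cfg.cytokine_umi_range
    u_mid = 0.5 * (u_lo + u_hi)

    coords: list[HexCoord] = [
        (r, c)
        for r in range(cfg.n_rows)
        for c in range(cfg.n_cols)
        if (r + c) % 2 == 0
    ]
    n_spots = len(coords)
    layers = [_layer_of_row(r, cfg) for r, _ in coords]
    epidermal = np.array(
        [l in ("upper epidermis", "middle epidermis", "basal epidermis") for l in layers]
    )
    coord_row = {coord: i for i, coord in enumerate(coords)}

    gt_spots: dict[str, dict[str, list[tuple[int, int, int]]]] = {
        cyt: {} for cyt in cfg.cytokine_names
    }

    blocks = []
    spot_rows = []
    meta_rows = []
    diseases = ("LP", "AD", "Pso")
    for si in range(cfg.n_samples):
        sample_id = f"S{si + 1:02d}"
        rng = np.random.default_rng([cfg.seed, si])
        mat = np.zeros((n_spots, n_genes), dtype=np.int64)
        field = _responder_field(rng, cfg, coords)

        # background genes everywhere
        for gname in [g for g in genes if g.startswith("BGGENE")]:
            mat[:, gene_idx[gname]] = _nb_draw(
                rng, np.full(n_spots, cfg.baseline_mean), cfg.nb_dispersion
            )
        for i in range(cfg.mt_gene_count):
            mat[:, gene_idx[f"MT-SIM{i + 1}"]] = _nb_draw(
                rng, np.full(n_spots, cfg.mt_mean), cfg.nb_dispersion
            )
        mat[:, gene_idx[cfg.housekeeping_gene]] = _nb_draw(
            rng, np.full(n_spots, cfg.housekeeping_mean), cfg.nb_dispersion
        )
        for m in cfg.marker_genes:
            mat[:, gene_idx[m]] = _nb_draw(
                rng, np.full(n_spots, cfg.marker_background_mean), cfg.nb_dispersion
            )

        # plant cytokine+ spots in the epidermis and amplify their responders
        epi_depth = sum(cfg.layer_widths[:3])
        if cfg.seed_margin > 0:
            m = cfg.seed_margin
            rows_arr = np.array([r for r, _ in coords])
            cols_arr = np.array([c for _, c in coords])
            eligible = (
                epidermal
                & (rows_arr >= m)
                & (rows_arr <= epi_depth - 1 - m)
                & (cols_arr >= 2 * m)  # hex ball spans +-2r columns
                & (cols_arr <= cfg.n_cols - 1 - 2 * m)
            )
        else:
            eligible = epidermal
        for cyt in cfg.cytokine_names:
            radius = cfg.true_radius[cyt]
            positive = eligible & (rng.random(n_spots) < cfg.cytokine_spot_rate)
            pos_idx = np.flatnonzero(positive)
            if cfg.max_seeds_per_sample is not None:
                pos_idx = pos_idx[
                    rng.permutation(len(pos_idx))[: cfg.max_seeds_per_sample]
                ]
                pos_idx.sort()
            umis = rng.integers(u_lo, u_hi + 1, size=len(pos_idx))
            planted = []
            local_load = np.zeros(n_spots)
            for spot_i, u in zip(pos_idx, umis):
                r0, c0 = coords[spot_i]
                mat[spot_i, gene_idx[cyt]] = u
                planted.append((r0, c0, int(u)))
                # leukocyte evidence co-located with the cytokine transcript
                marker = cfg.marker_genes[int(spot_i) % len(cfg.marker_genes)]
                mat[spot_i, gene_idx[marker]] += 1
                for dj, di in hex_offsets(radius):
                    tgt = (r0 + dj, c0 + di)
                    if tgt in coord_row:
                        local_load[coord_row[tgt]] += u
            gt_spots[cyt][sample_id] = planted
            # the induced response adds to (not multiplies) the patchy
            # baseline: cytokine signal is clean, background is noisy
            ball = 3 * radius * radius + 3 * radius + 1
            budget_scale = (
                cfg.response_budget_spots / ball
                if cfg.response_budget_spots is not None
                else 1.0
            )
            induced_mean = (
                cfg.baseline_mean
                * (cfg.amplification - 1.0)
                * budget_scale
                * local_load
                / u_mid
            )
            for gname in responders[cyt]:
                mat[:, gene_idx[gname]] = _nb_draw(
                    rng, cfg.baseline_mean * field, cfg.nb_dispersion
                ) + rng.poisson(induced_mean)

        blocks.append(sparse.csr_matrix(mat))
        for (r, c), layer in zip(coords, layers):
            spot_rows.append(
                (sample_id, f"BC{r:03d}X{c:03d}-1", 1, r, c, layer)
            )
        meta_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": f"P{si // 2 + 1:02d}",
                "project_id": f"PRJ{si // 4 + 1}",
                "disease": diseases[(si // 2) % 3],
                "condition": "lesional",
            }
        )

    ds = SpotDataset(
        counts=sparse.vstack(blocks, format="csr"),
        genes=pd.Index(genes),
        spots=pd.DataFrame(
            spot_rows,
            columns=["sample_id", "barcode", "in_tissue", "array_row", "array_col", "layer"],
        ),
        meta=pd.DataFrame(meta_rows).set_index("sample_id"),
    )
    ds.validate()

    planted_fc = {
        cyt: {g: 2.5 if cyt != "IL13" else 2.0 for g in responders[cyt]}
        for cyt in cfg.cytokine_names
    }
    gt = GroundTruth(
        cytokine_spots=gt_spots,
        true_radius=dict(cfg.true_radius),
        responder_genes={c: list(v) for c, v in responders.items()},
        planted_log2fc=planted_fc,
    )
    return ds, gt


def simulate_stim_table(
    gt: GroundTruth,
    noise_sd: float = 0.1,
    n_decoys: int = 20,
    cross_genes: dict[str, list[str]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Synthetic in-vitro stimulation DEG table.

    Planted responder genes receive a log2FC safely above the filter
    threshold with tiny p-values; decoys receive sub-threshold effects or
    non-significant p-values.  ``cross_genes`` (cytokine -> genes) plants
    filter-passing rows for the same gene under several cytokines, to be
    removed by cross-signature purification downstream.
    """
    gen = np.random.default_rng(rng)
    rows = []
    for cyt, fc_by_gene in gt.planted_log2fc.items():
        for gene, fc in fc_by_gene.items():
            rows.append(
                {
                    "gene": gene,
                    "cytokine": cyt,
                    "log2FC": fc + abs(gen.normal(0, noise_sd)),
                    "p_value": 10 ** gen.uniform(-8, -4),
                    "adj_p_value": 10 ** gen.uniform(-6, -3),
                }
            )
        for d in range(n_decoys):
            kind = d % 3
            rows.append(
                {
                    "gene": f"DECOY-{cyt}-{d + 1:02d}",
                    "cytokine": cyt,
                    # sub-threshold FC, or significant FC with a bad p-value
                    "log2FC": gen.uniform(-0.5, 0.5) if kind != 2 else gen.uniform(2, 4),
                    "p_value": 1e-4 if kind != 1 else gen.uniform(0.2, 0.9),
                    "adj_p_value": 1e-3 if kind != 2 else gen.uniform(0.1, 0.9),
                }
            )
    if cross_genes:
        for cyt, gns in cross_genes.items():
            for gene in gns:
                rows.append(
                    {
                        "gene": gene,
                        "cytokine": cyt,
                        "log2FC": 3.0 + abs(gen.normal(0, noise_sd)),
                        "p_value": 1e-6,
                        "adj_p_value": 1e-5,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "cytokine", "log2FC", "p_value", "adj_p_value"])
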