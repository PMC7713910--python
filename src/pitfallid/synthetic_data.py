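"""Synthetic multi-site specimen datasets with known ground truth.

Emulates the statistical shape of a continental pitfall-trap survey: a few
thousand specimens from ~tens of species, abundances strongly skewed (most
species rare), species feature distributions hierarchically correlated
(congeners resemble each other more than species from different tribes), and
each collection site hosting a small local species pool.  Also renders
ellipse-based batch "photographs" with analytic ground truth so the imaging
pipeline can be validated end to end without real photographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .manifest import N_FEATURES, feature_names
from .taxonomy import DEFAULT_RANKS, TaxonomyTable


class SyntheticError(ValueError):
    """Infeasible synthetic configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; ``seed`` fixes all randomness.

    ``rank_counts`` gives the number of distinct taxa at each rank, aligned
    with ``ranks`` (most specific first) and non-increasing.  ``drift_scales``
    set the standard deviation of the mean-vector random walk applied at each
    rank while descending the taxonomy, so larger values at coarse ranks
    separate higher clades more strongly.
    """

    n_species: int = 12
    ranks: tuple[str, ...] = DEFAULT_RANKS
    rank_counts: tuple[int, ...] = (12, 12, 5, 4, 4, 2)
    drift_scales: tuple[float, ...] = (0.15, 0.05, 0.35, 0.2, 0.25, 0.4)
    within_sd: float = 1.0
    abundance_law: str = "geometric"
    abundance_param: float = 0.8
    n_specimens: int = 600
    n_sites: int = 12
    pool_size_range: tuple[int, int] = (1, 7)
    pool_size_mean: float = 3.0
    n_trapping_events: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_specimens < 1 or self.n_sites < 1:
            raise SyntheticError("all counts must be positive")
        if len(self.rank_counts) != len(self.ranks) or len(self.drift_scales) != len(self.ranks):
            raise SyntheticError("rank_counts/drift_scales must align with ranks")
        if self.rank_counts[0] != self.n_species:
            raise SyntheticError("rank_counts[0] must equal n_species")
        if any(c < 1 for c in self.rank_counts):
            raise SyntheticError("rank counts must be positive")
        if any(a < b for a, b in zip(self.rank_counts[:-1], self.rank_counts[1:])):
            raise SyntheticError(
                "rank_counts must be non-increasing from species upward"
            )
        if any(s < 0 for s in self.drift_scales) or self.within_sd < 0:
            raise SyntheticError("scales must be >= 0")
        lo, hi = self.pool_size_range
        if not (1 <= lo <= hi):
            raise SyntheticError("invalid pool size range")
        if not (lo <= self.pool_size_mean <= hi):
            raise SyntheticError("pool_size_mean outside pool_size_range")
        if self.abundance_law not in ("geometric", "log-series"):
            raise SyntheticError(f"unknown abundance law {self.abundance_law!r}")


#: Test-scale preset: ~600 specimens, 12 species across 3 subfamilies,
#: 12 sites.  Abundance ratio 0.8 leaves roughly 7 species common enough to
#: train on and ~5 rare ("novel") species.
REDUCED_PRESET = SyntheticConfig()

#: Full-scale preset mirroring the survey this generator emulates: 3,270
#: specimens, 64 species / 32 genera / 19 tribes / 8 subfamilies, 18 sites,
#: 398 trapping events.  Abundance ratio 0.91 puts ~60% of species at <=30
#: observations, leaving ~25 trainable species.
EMULATION_PRESET = SyntheticConfig(
    n_species=64,
    rank_counts=(64, 64, 32, 26, 19, 8),
    n_specimens=3270,
    n_sites=18,
    abundance_param=0.91,
    n_trapping_events=398,
)

#: Bayes-separable limit: species means far apart relative to within-species
#: scatter, so any competent classifier should approach perfect accuracy.
SEPARABLE_PRESET = SyntheticConfig(
    n_species=8,
    rank_counts=(8, 8, 4, 3, 3, 2),
    drift_scales=(2.0, 0.5, 2.0, 1.0, 1.0, 1.5),
    n_specimens=400,
    n_sites=6,
    abundance_param=0.9,
)

#: Zero-signal limit: all species share one mean, so no classifier can beat
#: the most-common-species baseline except by chance.
ZERO_SIGNAL_PRESET = SyntheticConfig(
    n_species=5,
    rank_counts=(5, 5, 3, 3, 2, 2),
    drift_scales=(0.0,) * 6,
    n_specimens=800,
    n_sites=5,
    abundance_param=0.5,
)


def _abundance_probs(config: SyntheticConfig) -> np.ndarray:
    i = np.arange(config.n_species, dtype=float)
    if config.abundance_law == "geometric":
        w = config.abundance_param**i
    else:  # log-series
        w = config.abundance_param ** (i + 1) / (i + 1)
    return w / w.sum()


def make_taxonomy(config: SyntheticConfig, rng: np.random.Generator | None = None) -> TaxonomyTable:
    """Random nested taxonomy with exactly ``rank_counts`` taxa per rank."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ranks = config.ranks
    counts = config.rank_counts
    # child -> parent assignment per adjacent rank pair; surjective by
    # construction.  The first c_parent children anchor distinct parents and
    # the remainder attach to random parents, so under a rank-abundance law
    # (species index ~ rarity) every rare species shares its higher taxa
    # with a more common anchor species — as in real surveys, where rare
    # species are usually congeners of common ones.
    parent_of: list[np.ndarray] = []
    for c_child, c_parent in zip(counts[:-1], counts[1:]):
        assign = np.concatenate(
            [np.arange(c_parent), rng.integers(0, c_parent, c_child - c_parent)]
        )
        parent_of.append(assign)
    labels = {
        rank: [f"{rank}_{j + 1:03d}" for j in range(c)]
        for rank, c in zip(ranks, counts)
    }
    rows = []
    for s in range(config.n_species):
        idx = s
        row = {ranks[0]: labels[ranks[0]][s]}
        for level in range(len(ranks) - 1):
            idx = int(parent_of[level][idx])
            row[ranks[level + 1]] = labels[ranks[level + 1]][idx]
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(ranks))
    return TaxonomyTable(table=table, ranks=ranks)


def species_means(
    tax: TaxonomyTable, config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-species 68-d mean vectors built by random-walk drift down the taxonomy."""
    ranks = tax.ranks
    scales = dict(zip(config.ranks, config.drift_scales))
    means: dict[tuple[str, str], np.ndarray] = {}
    # top rank drifts from the origin; every lower rank drifts from its parent
    for level in range(len(ranks) - 1, -1, -1):
        rank = ranks[level]
        seen: list[str] = []
        for lab in tax.table[rank]:
            if lab not in seen:
                seen.append(lab)
        for lab in seen:
            if level == len(ranks) - 1:
                parent_mean = np.zeros(N_FEATURES)
            else:
                row = tax.table[tax.table[rank] == lab].iloc[0]
                parent_mean = means[(ranks[level + 1], row[ranks[level + 1]])]
            means[(rank, lab)] = parent_mean + rng.normal(
                0.0, scales[rank], N_FEATURES
            )
    return {sp: means[(ranks[0], sp)] for sp in tax.species}


def sample_feature_table(
    tax: TaxonomyTable,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Specimens x (68 features + species) table with hierarchical class structure.

    Class-conditional Gaussians: each species' mean is the endpoint of a
    drift walk down the taxonomy (congeners end up closer than cross-tribe
    species); within-species scatter is spherical with sd ``within_sd``.
    Abundances follow the configured skewed law.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    means = species_means(tax, config, rng)
    probs = _abundance_probs(config)
    counts = rng.multinomial(config.n_specimens, probs)
    blocks, labels = [], []
    for sp, cnt in zip(tax.species, counts):
        if cnt == 0:
            continue
        blocks.append(means[sp] + rng.normal(0.0, config.within_sd, (cnt, N_FEATURES)))
        labels.extend([sp] * cnt)
    X = np.vstack(blocks)
    order = rng.permutation(len(X))
    frame = pd.DataFrame(X[order], columns=feature_names())
    frame.insert(0, "specimen_id", [f"syn_{i + 1:05d}" for i in range(len(X))])
    frame["species"] = np.asarray(labels, dtype=object)[order]
    return frame.reset_index(drop=True)


def assign_sites(
    table: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Draw per-site species pools and assign every specimen to a matching site.

    Pool sizes are ``lo + Binomial(hi - lo, p)`` with ``p`` chosen so the
    expected size equals ``pool_size_mean``.  Every species present in the
    table is guaranteed a site (pools are topped up within the size range);
    each specimen then lands uniformly at random on a site whose pool
    contains its species.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    species = list(pd.unique(table["species"]))
    lo, hi = config.pool_size_range
    if config.n_sites * hi < len(species):
        raise SyntheticError(
            f"pool range {config.pool_size_range} cannot cover {len(species)} "
            f"species across {config.n_sites} sites"
        )
    site_ids = [f"site_{k + 1:02d}" for k in range(config.n_sites)]
    p = 0.0 if hi == lo else (config.pool_size_mean - lo) / (hi - lo)
    sizes = lo + rng.binomial(hi - lo, p, size=config.n_sites)
    pools: dict[str, list[str]] = {s: [] for s in site_ids}
    # coverage pass: every species gets at least one site
    shuffled = list(species)
    rng.shuffle(shuffled)
    for sp in shuffled:
        open_sites = [s for s in site_ids if len(pools[s]) < sizes[site_ids.index(s)]]
        if not open_sites:
            open_sites = [s for s in site_ids if len(pools[s]) < hi]
        if not open_sites:
            raise SyntheticError("pool capacity exhausted before covering all species")
        pools[rng.choice(open_sites)].append(sp)
    # fill remaining sampled capacity with abundance-weighted extras
    freq = table["species"].value_counts()
    weights = np.array([freq.get(sp, 0) + 1.0 for sp in species])
    weights = weights / weights.sum()
    for k, site in enumerate(site_ids):
        target = min(int(sizes[k]), len(species))
        while len(pools[site]) < target:
            cand = rng.choice(species, p=weights)
            if cand not in pools[site]:
                pools[site].append(cand)
    pools = {s: sorted(pool) for s, pool in pools.items() if pool}
    sites_of: dict[str, list[str]] = {}
    for site, pool in pools.items():
        for sp in pool:
            sites_of.setdefault(sp, []).append(site)
    out = table.copy()
    out["site"] = [rng.choice(sites_of[sp]) for sp in table["species"]]
    return pools, out


# ---------------------------------------------------------------------------
# Rendered batch images


@dataclass
class RenderSpecimen:
    """Analytic description of one rendered specimen (an ellipse blob)."""

    specimen_id: str
    a_mm: float  # semi-major axis
    b_mm: float  # semi-minor axis
    angle_deg: float
    dorsal_color: tuple[int, int, int]
    ventral_color: tuple[int, int, int]

    @property
    def area_mm2(self) -> float:
        return math.pi * self.a_mm * self.b_mm


def sample_render_specimens(
    n: int,
    rng: np.random.Generator,
    a_range: tuple[float, float] = (2.5, 5.0),
    aspect_range: tuple[float, float] = (1.6, 3.0),
    event_id: str = "event",
) -> list[RenderSpecimen]:
    """Random dark-bodied ellipse specimens with plausible beetle proportions."""
    out = []
    for k in range(n):
        a = rng.uniform(*a_range)
        b = a / rng.uniform(*aspect_range)
        dorsal = tuple(int(v) for v in rng.integers(15, 90, 3))
        ventral = tuple(min(255, c + int(rng.integers(10, 40))) for c in dorsal)
        out.append(
            RenderSpecimen(
                specimen_id=f"{event_id}_{k + 1:03d}",
                a_mm=float(a),
                b_mm=float(b),
                angle_deg=float(rng.uniform(0, 180)),
                dorsal_color=dorsal,
                ventral_color=ventral,
            )
        )
    return out


def _render_view(
    specimens: list[RenderSpecimen],
    layout: dict,
    rng: np.random.Generator,
    view: str,
) -> np.ndarray:
    res = float(layout.get("resolution", 12.0))
    n_cols = int(layout.get("n_cols", 4))
    cell_mm = float(layout.get("cell_mm", 14.0))
    margin_mm = float(layout.get("margin_mm", 1.0))
    cell_px = int(round(cell_mm * res))
    n_rows = int(math.ceil(len(specimens) / n_cols))
    H, W = n_rows * cell_px, n_cols * cell_px
    img = np.clip(rng.normal(245.0, 2.0, (H, W, 3)), 232, 255)
    for k, sp in enumerate(specimens):
        if 2 * max(sp.a_mm, sp.b_mm) + 2 * margin_mm > cell_mm:
            raise SyntheticError(
                f"specimen {sp.specimen_id} (2a={2 * sp.a_mm:.1f} mm) does not "
                f"fit a {cell_mm} mm cell; overlap would result"
            )
        row, col = divmod(k, n_cols)
        cr = row * cell_px + cell_px // 2
        cc = col * cell_px + cell_px // 2
        angle = sp.angle_deg
        color = sp.dorsal_color
        if view == "ventral":
            cc = (W - 1) - cc
            angle = -angle
            color = sp.ventral_color
        rr, cols_ = draw_ellipse(
            cr,
            cc,
            sp.b_mm * res,
            sp.a_mm * res,
            shape=(H, W),
            rotation=math.radians(angle),
        )
        noise = rng.normal(0.0, 2.0, (len(rr), 3))
        img[rr, cols_] = np.clip(np.asarray(color, float) + noise, 0, 255)
    return np.rint(img).astype(np.uint8)


def render_batch_image(
    specimens: list[RenderSpecimen],
    layout: dict | None = None,
    seed: int = 0,
    event_id: str = "event",
):
    """Render the dorsal/ventral image pair for one trapping event.

    Returns ``(dorsal, ventral, truth)`` where ``truth`` is a DataFrame of
    the analytic per-specimen ground truth (area, axis lengths, aspect
    ratio, mean colors) against which measured values can be compared.
    """
    from .imaging import BatchImage

    layout = dict(layout or {})
    rng = np.random.default_rng(seed)
    res = float(layout.get("resolution", 12.0))
    n_cols = int(layout.get("n_cols", 4))
    cell_px = int(round(float(layout.get("cell_mm", 14.0)) * res))
    n_rows = int(math.ceil(len(specimens) / n_cols))
    width_px = n_cols * cell_px
    dorsal_px = _render_view(specimens, layout, rng, "dorsal")
    ventral_px = _render_view(specimens, layout, rng, "ventral")
    dorsal = BatchImage(dorsal_px, res, "dorsal", f"{event_id}_dorsal")
    ventral = BatchImage(ventral_px, res, "ventral", f"{event_id}_ventral")
    truth = pd.DataFrame(
        [
            {
                "specimen_id": sp.specimen_id,
                "center_row": (k // n_cols) * cell_px + cell_px // 2,
                "center_col": (k % n_cols) * cell_px + cell_px // 2,
                "ventral_center_col": (width_px - 1)
                - ((k % n_cols) * cell_px + cell_px // 2),
                "area_mm2": sp.area_mm2,
                "major_mm": 2 * sp.a_mm,
                "minor_mm": 2 * sp.b_mm,
                "aspect_ratio": sp.a_mm / sp.b_mm,
                "dorsal_R": sp.dorsal_color[0],
                "dorsal_G": sp.dorsal_color[1],
                "dorsal_B": sp.dorsal_color[2],
                "ventral_R": sp.ventral_color[0],
                "ventral_G": sp.ventral_color[1],
                "ventral_B": sp.ventral_color[2],
            }
            for k, sp in enumerate(specimens)
        ]
    )
    return dorsal, ventral, truth


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[TaxonomyTable, pd.DataFrame, dict[str, list[str]]]:
    """Taxonomy + feature table + site pools in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    tax = make_taxonomy(config, rng)
    table = sample_feature_table(tax, config, rng)
    pools, table = assign_sites(table, config, rng)
    return tax, table, pools


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
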