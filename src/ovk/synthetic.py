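"""Synthetic data generators with planted-truth ledgers.

Each generator produces inputs with the statistical structure the
corresponding analysis stage assumes — point-mutated opsin sequences,
multinomial read counts, Poisson-sampled retinal density surfaces,
Bernoulli psychometric trials, Gaussian-band spectra — and returns a
:class:`GeneratorLedger` recording the planted truths, so recovery tests
compare estimates against the ledger rather than hard-coded values.
All randomness flows from a single integer seed; identical
(scenario, seed) pairs reproduce outputs bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .opsin_sequences import OpsinSequence, assign_bovine_numbering, bovine_rhodopsin
from .retinal_topography import CountingSite
from .visual_models import DEFAULT_GRID, Spectrum


@dataclass
class GeneratorLedger:
    """Record of what a generator planted, for recovery testing."""

    scenario: str
    seed: Optional[int]
    truths: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Opsin sequences

def make_opsin_variant(
    reference: OpsinSequence,
    substitutions: Sequence[tuple[int, str]],
    variant_id: Optional[str] = None,
    bovine: Optional[str] = None,
) -> tuple[OpsinSequence, GeneratorLedger]:
    """Mutate a reference opsin at given bovine-numbered sites.

    Deterministic (no RNG).  Errors if a requested site falls in a gap of
    the reference's bovine alignment.
    """
    if bovine is None:
        bovine = bovine_rhodopsin()
    aln = assign_bovine_numbering(reference, bovine)
    seq = list(reference.amino_acids)
    planted = []
    for site, to_res in substitutions:
        idx = aln.query_index_of_site(site)
        if idx is None:
            raise ValueError(f"bovine site {site} is unmapped (gap) in {reference.id}")
        from_res = seq[idx]
        if from_res == to_res:
            raise ValueError(f"site {site} already carries {to_res}")
        planted.append({"bovine_site": site, "from_residue": from_res,
                        "to_residue": to_res})
        seq[idx] = to_res
    variant = OpsinSequence(
        variant_id or f"{reference.id}_variant",
        reference.opsin_class,
        "".join(seq),
    )
    ledger = GeneratorLedger("opsin_variant", None, {
        "reference_id": reference.id,
        "planted_substitutions": planted,
    })
    return variant, ledger


def synthetic_reference_opsin(opsin_class: str, seq_id: str,
                              planted_residues: Sequence[tuple[int, str]] = (),
                              bovine: Optional[str] = None) -> OpsinSequence:
    """A synthetic reference opsin on the bovine rhodopsin scaffold.

    Stand-in for reference species' opsins: the bovine sequence with
    specific residues planted at bovine-numbered sites (e.g. the S at
    site 299 that a rod-opsin reference carries).  Synthetic — it is a
    numbering scaffold, not any real species' opsin.
    """
    if bovine is None:
        bovine = bovine_rhodopsin()
    seq = list(bovine)
    for site, res in planted_residues:
        seq[site - 1] = res
    return OpsinSequence(seq_id, opsin_class, "".join(seq))


# ---------------------------------------------------------------------------
# Read counts

def make_read_counts(
    true_proportions: dict[str, float],
    cds_lengths: dict[str, int],
    gene_classes: dict[str, str],
    total_reads: int,
    seed: int,
    individual_id: str = "ind1",
) -> tuple[pd.DataFrame, GeneratorLedger]:
    """Multinomial read counts whose normalised proportions match the truth.

    Per-gene read probability ∝ proportion × CDS length, so that
    length-normalised counts estimate the planted proportions.
    """
    genes = list(true_proportions)
    props = np.array([true_proportions[g] for g in genes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("true proportions must sum to 1")
    lengths = np.array([cds_lengths[g] for g in genes], dtype=float)
    p_read = props * lengths
    p_read = p_read / p_read.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_reads, p_read)
    df = pd.DataFrame({
        "individual_id": individual_id,
        "gene_id": genes,
        "gene_class": [gene_classes[g] for g in genes],
        "reads": counts,
        "cds_length_bp": lengths.astype(int),
    })
    ledger = GeneratorLedger("read_counts", seed, {
        "individual_id": individual_id,
        "true_proportions": dict(true_proportions),
        "total_reads": total_reads,
    })
    return df, ledger


# ---------------------------------------------------------------------------
# Retinal counting sites

def elliptical_outline(semi_x_mm: float = 5.0, semi_y_mm: float = 4.0,
                       n_vertices: int = 96) -> Polygon:
    """Elliptical retina outline centred on the origin (temporal = +x)."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return Polygon(zip(semi_x_mm * np.cos(t), semi_y_mm * np.sin(t)))


def make_retina(
    peak_density: float,
    streak_elongation: float,
    background_density: float,
    seed: int,
    outline: Optional[Polygon] = None,
    grid_step_mm: float = 0.65,
    frame_area_mm2: float = 0.0025,
    cell_class: str = "ganglion",
    peak_centre: Optional[tuple[float, float]] = None,
    sigma_mm: float = 1.2,
    subsample: bool = True,
) -> tuple[list[CountingSite], GeneratorLedger]:
    """Counting sites from a streak-plus-temporal-peak density surface.

    density(x, y) = background + (peak − background) ·
        exp(−((x−x0)²/(2 (σ·elongation)²) + (y−y0)²/(2 σ²)))

    Elongation > 1 stretches the specialisation along the horizontal
    meridian (a streak); 1 gives a radially symmetric area centralis.
    Counts are Poisson(density × frame area) on a systematic grid with a
    random start; a half-step subsample around the true peak is appended
    when ``subsample`` (its sites carry grid_step/2).
    """
    if not peak_density > background_density > 0:
        raise ValueError("need peak > background > 0")
    if outline is None:
        outline = elliptical_outline()
    if peak_centre is None:
        minx, _, maxx, _ = outline.bounds
        peak_centre = (0.5 * maxx, 0.0)  # temporal
    x0, y0 = peak_centre
    sx = sigma_mm * streak_elongation
    sy = sigma_mm

    def density(x, y):
        return background_density + (peak_density - background_density) * np.exp(
            -((x - x0) ** 2 / (2 * sx ** 2) + (y - y0) ** 2 / (2 * sy ** 2)))

    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = outline.bounds
    start_x = minx + rng.uniform(0, grid_step_mm)
    start_y = miny + rng.uniform(0, grid_step_mm)
    sites = []
    for gx in np.arange(start_x, maxx, grid_step_mm):
        for gy in np.arange(start_y, maxy, grid_step_mm):
            if outline.contains(Point(gx, gy)):
                lam = density(gx, gy) * frame_area_mm2
                sites.append(CountingSite(
                    float(gx), float(gy), {cell_class: int(rng.poisson(lam))},
                    frame_area_mm2, grid_step_mm))
    if len(sites) < 50:
        raise ValueError(f"outline too small: only {len(sites)} sites on the grid")
    if subsample:
        half = grid_step_mm / 2.0
        for dx in (-half, 0.0, half):
            for dy in (-half, 0.0, half):
                px, py = x0 + dx, y0 + dy
                if outline.contains(Point(px, py)):
                    lam = density(px, py) * frame_area_mm2
                    sites.append(CountingSite(
                        float(px), float(py), {cell_class: int(rng.poisson(lam))},
                        frame_area_mm2, half))
    # true total population: integrate the surface on a fine raster
    fine = 0.05
    fx = np.arange(minx, maxx, fine) + fine / 2
    fy = np.arange(miny, maxy, fine) + fine / 2
    fxx, fyy = np.meshgrid(fx, fy)
    try:
        from shapely import contains_xy
        inside = contains_xy(outline, fxx, fyy)
    except ImportError:  # pragma: no cover
        inside = np.array([[outline.contains(Point(a, b)) for a in fx] for b in fy])
    true_total = float(np.sum(density(fxx, fyy)[inside]) * fine * fine)
    ledger = GeneratorLedger("retina", seed, {
        "cell_class": cell_class,
        "true_peak_density": float(density(x0, y0)),
        "peak_centre": [float(x0), float(y0)],
        "background_density": background_density,
        "streak_elongation": streak_elongation,
        "sigma_mm": sigma_mm,
        "true_total_population": true_total,
        "grid_step_mm": grid_step_mm,
        "frame_area_mm2": frame_area_mm2,
        "n_sites": len(sites),
    })
    return sites, ledger


# ---------------------------------------------------------------------------
# Behavioural trials

def make_trials(
    true_threshold_cpd: float,
    slope: float,
    frequencies: Sequence[float],
    n_per_frequency: int,
    seed: int,
    guess: float = 0.5,
    criterion: float = 0.62,
    fish_id: str = "fish1",
    treatment: str = "achromatic",
) -> tuple[pd.DataFrame, GeneratorLedger]:
    """Bernoulli choices from a logistic observer.

    The observer's ψ is parameterised so ψ(true_threshold) = criterion:
    α = t − ln((1 − c)/(c − γ)) / β.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if not freqs.min() <= true_threshold_cpd <= freqs.max():
        raise ValueError("planted threshold must lie within the frequency span")
    if slope <= 0:
        raise ValueError("slope must be positive")
    alpha = true_threshold_cpd - np.log((1 - criterion) / (criterion - guess)) / slope
    rng = np.random.default_rng(seed)
    rows = []
    for f in freqs:
        psi = guess + (1 - guess) / (1 + np.exp(slope * (f - alpha)))
        correct = rng.random(n_per_frequency) < psi
        rows.extend({"fish_id": fish_id, "treatment": treatment,
                     "spatial_frequency_cpd": float(f), "correct": int(c)}
                    for c in correct)
    df = pd.DataFrame(rows)
    ledger = GeneratorLedger("trials", seed, {
        "true_threshold_cpd": true_threshold_cpd,
        "slope": slope,
        "alpha": float(alpha),
        "guess": guess,
        "criterion": criterion,
        "n_per_frequency": n_per_frequency,
        "frequencies": list(map(float, freqs)),
    })
    return df, ledger


# ---------------------------------------------------------------------------
# Spectra

def make_spectra(
    band_centres: Sequence[float],
    band_widths: Sequence[float],
    seed: int = 0,
    band_amplitudes: Optional[Sequence[float]] = None,
    illuminant_slope: float = 0.0005,
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[Spectrum, Spectrum, GeneratorLedger]:
    """Gaussian-band reflectance plus a smooth positive illuminant.

    Reflectance is a sum of Gaussian bands clipped to [0, 1]; an empty
    band list gives a flat black surface.  The illuminant is flat with a
    mild linear tilt (arbitrary units).
    """
    grid = np.asarray(grid, dtype=float)
    if len(band_centres) != len(band_widths):
        raise ValueError("band_centres and band_widths must match in length")
    for c in band_centres:
        if not grid[0] <= c <= grid[-1]:
            raise ValueError(f"band centre {c} outside the grid")
    if band_amplitudes is None:
        band_amplitudes = [0.8] * len(band_centres)
    refl = np.zeros_like(grid)
    for c, w, a in zip(band_centres, band_widths, band_amplitudes):
        refl += a * np.exp(-((grid - c) ** 2) / (2 * w ** 2))
    refl = np.clip(refl, 0.0, 1.0)
    illum = 1.0 + illuminant_slope * (grid - grid[0])
    ledger = GeneratorLedger("spectra", seed, {
        "band_centres": list(map(float, band_centres)),
        "band_widths": list(map(float, band_widths)),
        "band_amplitudes": list(map(float, band_amplitudes)),
        "illuminant_slope": illuminant_slope,
    })
    return Spectrum(grid.copy(), refl), Spectrum(grid.copy(), illum), ledger


# ---------------------------------------------------------------------------
# Named scenarios (defaults follow the study conditions)

#: Overall opsin proportions used by the expression scenarios. The rod
#: share is the study mean; within double cones the genes follow the
#: group means; single cones (all SWS2B) take one third of the cone
#: share, mirroring the 2:1 double:single mosaic.
def _expression_truth(rod: float, dc_split: dict[str, float]) -> dict[str, float]:
    cone = 1.0 - rod
    sc = cone / 3.0
    dc = cone - sc
    out = {"RH1": rod, "SWS2B": sc}
    out.update({g: dc * f for g, f in dc_split.items()})
    return out


OPSIN_CDS_LENGTHS = {"RH1": 1062, "SWS2B": 1053, "RH2A": 1047,
                     "RH2C-1": 1044, "RH2C-2": 1044, "LWS": 1074}
OPSIN_GENE_CLASSES = {"RH1": "rod", "SWS2B": "single_cone", "RH2A": "double_cone",
                      "RH2C-1": "double_cone", "RH2C-2": "double_cone",
                      "LWS": "double_cone"}

SCENARIOS = {
    "aquarium_expression": {
        "kind": "expression",
        "true_proportions": _expression_truth(
            0.689, {"RH2A": 0.6030, "RH2C-2": 0.2738, "RH2C-1": 0.1214, "LWS": 0.0018}),
        "total_reads": 1_000_000,
    },
    "field_expression": {
        "kind": "expression",
        "true_proportions": _expression_truth(
            0.689, {"RH2A": 0.3504, "RH2C-2": 0.4589, "RH2C-1": 0.1734, "LWS": 0.0170}),
        "total_reads": 1_000_000,
    },
    "achromatic_acuity": {
        "kind": "trials",
        "true_threshold_cpd": 3.94, "slope": 1.2,
        "frequencies": np.arange(0.5, 5.0 + 1e-9, 0.5),
        "n_per_frequency": 110, "treatment": "achromatic",
    },
    "green_yellow_acuity": {
        "kind": "trials",
        "true_threshold_cpd": 1.71, "slope": 2.0,
        "frequencies": np.arange(0.5, 3.0 + 1e-9, 0.5),
        "n_per_frequency": 110, "treatment": "green_yellow",
    },
    "pink_purple_acuity": {
        "kind": "trials",
        "true_threshold_cpd": 1.89, "slope": 2.0,
        "frequencies": np.arange(0.5, 3.0 + 1e-9, 0.5),
        "n_per_frequency": 110, "treatment": "pink_purple",
    },
    "ganglion_streak": {
        "kind": "retina",
        "peak_density": 38_643.0, "background_density": 8_000.0,
        "streak_elongation": 3.0,
    },
}


def simulate(scenario: str, seed: int, outdir=None):
    """Generate a named scenario; optionally write files plus ledger.json."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    cfg = SCENARIOS[scenario]
    if cfg["kind"] == "expression":
        data, ledger = make_read_counts(
            cfg["true_proportions"], OPSIN_CDS_LENGTHS, OPSIN_GENE_CLASSES,
            cfg["total_reads"], seed)
        ledger.scenario = scenario
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            data.to_csv(outdir / "counts.tsv", sep="\t", index=False)
            ledger.to_json(outdir / "ledger.json")
        return data, ledger
    if cfg["kind"] == "trials":
        data, ledger = make_trials(
            cfg["true_threshold_cpd"], cfg["slope"], cfg["frequencies"],
            cfg["n_per_frequency"], seed, treatment=cfg["treatment"])
        ledger.scenario = scenario
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            data.to_csv(outdir / "trials.csv", index=False)
            ledger.to_json(outdir / "ledger.json")
        return data, ledger
    if cfg["kind"] == "retina":
        sites, ledger = make_retina(
            cfg["peak_density"], cfg["streak_elongation"],
            cfg["background_density"], seed)
        ledger.scenario = scenario
        if outdir is not None:
            from .retinal_topography import sites_to_csv
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            sites_to_csv(sites, outdir / "sites.csv")
            ledger.to_json(outdir / "ledger.json")
        return sites, ledger
    raise AssertionError("unreachable")
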