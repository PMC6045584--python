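"""Seeded synthetic-screen and synthetic-proteomics generators.

Every generator is a pure function of its configuration and seed and
returns ground truth alongside the data, so each pipeline stage can be
checked against known parameters without any external dataset.

The screen generator emulates a 384-well CellTiter-Glo viability
screen: an 8-point dose titration (0.5-1000 nM by default), triplicate
screens per cell line, DMSO negative-control and maximum-kill
positive-control wells, multiplicative lognormal read noise (luminescence
noise scales with signal), and optional genotype-linked sensitivity
shifts (e.g. a marker that divides the ED50 of selected drugs). True
per-(cell line, drug) AUC values are computed here by dense trapezoid
quadrature on the true parameters — an oracle path deliberately
independent of the fitting/scoring code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    CellLineAnnotation,
    CompoundEntry,
    CompoundLibrary,
    N_COLS,
    N_ROWS,
    PlateLayout,
    Replicate,
    ScreenDataset,
    WellAssignment,
    WellMeasurement,
    write_annotations,
    write_layouts,
    write_library,
    write_screen_datasets,
)
from .proteomics import LFQMatrix

__all__ = [
    "DOSE_SERIES",
    "GenotypeEffect",
    "ScreenSimConfig",
    "SimTruth",
    "true_auc_unscaled",
    "true_auc_scaled",
    "simulate_screen",
    "simulate_proteomics",
    "make_fixture_bundle",
]

# the standard 8-point titration used throughout, in nM
DOSE_SERIES: tuple[float, ...] = (0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)

BASE_LUMINESCENCE = 1000.0  # RLU of an untreated well
POSITIVE_KILL_FRACTION = 0.02  # positive controls retain 2% signal


@dataclass(frozen=True)
class GenotypeEffect:
    """Sensitivity shift linked to a genotype marker.

    ``fraction`` of cell lines carry the marker; for those lines the
    ED50 of the targeted drugs is divided by ``ed50_fold`` and the upper
    asymptote shifted down by ``d_shift``. ``drugs=None`` targets every
    drug in the simulated library.
    """

    fraction: float
    ed50_fold: float = 1.0
    d_shift: float = 0.0
    drugs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.ed50_fold <= 0:
            raise ValueError("ed50_fold must be > 0")
        if self.drugs is not None:
            object.__setattr__(self, "drugs", tuple(self.drugs))


@dataclass(frozen=True)
class ScreenSimConfig:
    n_cell_lines: int = 6
    n_drugs: int = 4
    dose_series: tuple[float, ...] = DOSE_SERIES
    n_replicates: int = 3
    noise_sigma: float = 0.1
    n_dmso_wells: int = 16
    n_positive_wells: int = 16
    genotype_effects: Mapping[str, GenotypeEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        doses = tuple(float(c) for c in self.dose_series)
        if any(c <= 0 for c in doses) or any(
            b <= a for a, b in zip(doses, doses[1:])
        ):
            raise ValueError("dose series must be strictly increasing and positive")
        for name in ("n_cell_lines", "n_drugs", "n_replicates",
                     "n_dmso_wells", "n_positive_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n_wells = (
            self.n_drugs * len(doses) + self.n_dmso_wells + self.n_positive_wells
        )
        if n_wells > N_ROWS * N_COLS:
            raise ValueError(
                f"{n_wells} wells required but a 384-well plate has {N_ROWS * N_COLS}"
            )
        object.__setattr__(self, "dose_series", doses)
        object.__setattr__(self, "genotype_effects", dict(self.genotype_effects))


@dataclass
class SimTruth:
    """Generating parameters and oracle AUCs for a simulated study."""

    params: dict[tuple[str, str], tuple[float, float, float]]  # (b, d, e)
    auc_unscaled: dict[tuple[str, str], float]
    auc_scaled: dict[tuple[str, str], float]
    genotype_flags: dict[str, dict[str, str]]
    protein_delta: dict[str, float] = field(default_factory=dict)


def _three_pl(c, b, d, e):
    c = np.asarray(c, dtype=float)
    return d / (1.0 + (c / e) ** b)


def true_auc_unscaled(
    b: float, d: float, e: float, c_min: float, c_max: float, n_grid: int = 100_001
) -> float:
    """Oracle AUC: trapezoid quadrature of clip(SF, 0, 1) on the log axis."""
    u = np.linspace(np.log(c_min), np.log(c_max), n_grid)
    sf = np.clip(_three_pl(np.exp(u), b, d, e), 0.0, 1.0)
    return float(np.trapezoid(sf, u) / (u[-1] - u[0]))


def true_auc_scaled(
    b: float, d: float, e: float, c_min: float, c_max: float, n_grid: int = 100_001
) -> float:
    """Oracle scaled AUC via trapezoid quadrature on the log axis."""
    u = np.linspace(np.log(c_min), np.log(c_max), n_grid)
    a = np.clip(1.0 - _three_pl(np.exp(u), b, d, e), 0.0, 1.0)
    excess = np.maximum(0.0, a - max(0.0, a[0]))
    return float(1.0 - np.trapezoid(excess, u) / (u[-1] - u[0]))


def _build_layout(plate_id: str, cfg: ScreenSimConfig, drug_ids: Sequence[str]) -> PlateLayout:
    """Row-major assignment: compound wells, then DMSO, then positive controls."""
    coords = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
    wells: dict[tuple[int, int], WellAssignment] = {}
    i = 0
    for drug in drug_ids:
        for conc in cfg.dose_series:
            wells[coords[i]] = WellAssignment("compound", drug, conc)
            i += 1
    for _ in range(cfg.n_dmso_wells):
        wells[coords[i]] = WellAssignment("dmso")
        i += 1
    for _ in range(cfg.n_positive_wells):
        wells[coords[i]] = WellAssignment("positive")
        i += 1
    return PlateLayout(plate_id=plate_id, wells=wells)


def _draw_true_params(
    rng: np.random.Generator, cfg: ScreenSimConfig,
    cell_lines: Sequence[str], drug_ids: Sequence[str],
) -> tuple[dict, dict]:
    """Random generating parameters plus genotype flags and shifts."""
    c_min, c_max = cfg.dose_series[0], cfg.dose_series[-1]
    params: dict[tuple[str, str], tuple[float, float, float]] = {}
    for line in cell_lines:
        for drug in drug_ids:
            b = float(rng.uniform(0.8, 2.5))
            d = float(rng.uniform(0.92, 1.05))
            # log-uniform ED50 from the lowest dose to 10x the top dose:
            # spans profound sensitivity through near-inactivity
            e = float(np.exp(rng.uniform(np.log(c_min), np.log(10.0 * c_max))))
            params[(line, drug)] = (b, d, e)

    flags: dict[str, dict[str, str]] = {line: {} for line in cell_lines}
    for marker in sorted(cfg.genotype_effects):
        eff = cfg.genotype_effects[marker]
        n_pos = int(round(eff.fraction * len(cell_lines)))
        carriers = set(
            rng.choice(len(cell_lines), size=n_pos, replace=False).tolist()
        )
        targeted = eff.drugs if eff.drugs is not None else tuple(drug_ids)
        for idx, line in enumerate(cell_lines):
            flags[line][marker] = "positive" if idx in carriers else "negative"
            if idx in carriers:
                for drug in targeted:
                    if (line, drug) in params:
                        b, d, e = params[(line, drug)]
                        params[(line, drug)] = (
                            b, max(0.0, d - eff.d_shift), e / eff.ed50_fold
                        )
    return params, flags


def _simulate_from_params(
    rng: np.random.Generator,
    cfg: ScreenSimConfig,
    params: Mapping[tuple[str, str], tuple[float, float, float]],
    cell_lines: Sequence[str],
    drug_ids: Sequence[str],
    targets: Mapping[str, str] | None = None,
) -> dict[str, ScreenDataset]:
    library = CompoundLibrary(
        tuple(
            CompoundEntry(drug, (targets or {}).get(drug, ""), cfg.dose_series)
            for drug in drug_ids
        )
    )
    datasets: dict[str, ScreenDataset] = {}
    for line in cell_lines:
        replicates = []
        for rep_idx in range(1, cfg.n_replicates + 1):
            plate_id = f"{line}_r{rep_idx}"
            layout = _build_layout(plate_id, cfg, drug_ids)
            measurements = []
            for coord in sorted(layout.wells):
                w = layout.wells[coord]
                noise = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
                if w.role == "compound":
                    b, d, e = params[(line, w.compound_id)]
                    signal = BASE_LUMINESCENCE * float(
                        _three_pl(w.conc_nM, b, d, e)
                    )
                elif w.role == "dmso":
                    signal = BASE_LUMINESCENCE
                else:  # positive control: near-complete kill
                    signal = BASE_LUMINESCENCE * POSITIVE_KILL_FRACTION
                measurements.append(
                    WellMeasurement(plate_id, coord, signal * noise)
                )
            replicates.append(
                Replicate(rep_idx, tuple(measurements), {plate_id: layout})
            )
        datasets[line] = ScreenDataset(line, tuple(replicates), library)
    return datasets


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[dict[str, ScreenDataset], list[CellLineAnnotation], SimTruth]:
    """Simulate a full replicate screen of a drug x cell-line panel.

    Returns one :class:`ScreenDataset` per cell line, annotations
    carrying the simulated genotype flags, and the :class:`SimTruth`
    with generating parameters and oracle AUC values. Deterministic
    given the config (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    cell_lines = [f"CL{i + 1:03d}" for i in range(cfg.n_cell_lines)]
    drug_ids = [f"DRUG{j + 1:03d}" for j in range(cfg.n_drugs)]
    params, flags = _draw_true_params(rng, cfg, cell_lines, drug_ids)
    datasets = _simulate_from_params(rng, cfg, params, cell_lines, drug_ids)
    c_min, c_max = cfg.dose_series[0], cfg.dose_series[-1]
    truth = SimTruth(
        params=dict(params),
        auc_unscaled={
            k: true_auc_unscaled(*v, c_min, c_max) for k, v in params.items()
        },
        auc_scaled={
            k: true_auc_scaled(*v, c_min, c_max) for k, v in params.items()
        },
        genotype_flags=flags,
    )
    annotations = [
        CellLineAnnotation(line, "simulated", flags[line]) for line in cell_lines
    ]
    return datasets, annotations, truth


def simulate_proteomics(
    n_proteins: int,
    n_spiked: int,
    delta: float,
    sigma: float,
    n_per_group: int,
    seed: int,
    baseline: float = 25.0,
) -> tuple[LFQMatrix, SimTruth]:
    """Simulate a log2 LFQ matrix with spiked differential proteins.

    Null proteins draw both groups from Normal(baseline_i, sigma); the
    first ``n_spiked`` proteins are shifted by +/-delta in group B (half
    up, half down). Protein-level baselines vary to mimic the LFQ
    dynamic range. Deterministic given the seed.
    """
    if n_spiked > n_proteins:
        raise ValueError("n_spiked cannot exceed n_proteins")
    if n_per_group < 2 or n_proteins < 1:
        raise ValueError("need n_per_group >= 2 and n_proteins >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    import pandas as pd

    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    baselines = baseline + rng.normal(0.0, 3.0, size=n_proteins)
    true_delta = np.zeros(n_proteins)
    true_delta[: n_spiked // 2] = delta
    true_delta[n_spiked // 2 : n_spiked] = -delta
    vals = rng.normal(0.0, sigma, size=(n_proteins, 2 * n_per_group))
    vals += baselines[:, None]
    vals[:, n_per_group:] += true_delta[:, None]
    matrix = LFQMatrix(
        values=pd.DataFrame(vals, index=proteins, columns=samples),
        groups={s: ("A" if s.startswith("A") else "B") for s in samples},
    )
    truth = SimTruth(
        params={}, auc_unscaled={}, auc_scaled={}, genotype_flags={},
        protein_delta={p: float(dv) for p, dv in zip(proteins, true_delta)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture bundle: a small hand-designed panel with a BRCA-like contrast
# ---------------------------------------------------------------------------

FIXTURE_CELL_LINES = (
    "OS-HRD",      # HR-defective analogue: profoundly PARPi-sensitive
    "OS-HRD-REV",  # engineered revertant analogue: PARPi-resistant
    "OS-A", "OS-B", "OS-C", "OS-D",
)
FIXTURE_DRUGS = ("PARPI-A", "PARPI-B", "PARPI-C", "KINI-D")
FIXTURE_PARPI = FIXTURE_DRUGS[:3]

# per-line PARPi ED50 (nM); the HR-defective line is far below the rest
# and the revertant far above, mirroring a BRCA1-mutant / revertant pair
_FIXTURE_PARPI_ED50 = {
    "OS-HRD": 2.0,
    "OS-HRD-REV": 50_000.0,
    "OS-A": 400.0,
    "OS-B": 1200.0,
    "OS-C": 3000.0,
    "OS-D": 9000.0,
}
# every line responds to the kinase-inhibitor control drug, so replicate
# correlations are informative even for PARPi-resistant lines
_FIXTURE_KINI_ED50 = {
    "OS-HRD": 30.0,
    "OS-HRD-REV": 60.0,
    "OS-A": 15.0,
    "OS-B": 45.0,
    "OS-C": 90.0,
    "OS-D": 25.0,
}


def _fixture_params() -> dict[tuple[str, str], tuple[float, float, float]]:
    params = {}
    for line in FIXTURE_CELL_LINES:
        for i, drug in enumerate(FIXTURE_PARPI):
            # small deterministic slope variation between the three PARPi
            params[(line, drug)] = (1.4 + 0.1 * i, 1.0, _FIXTURE_PARPI_ED50[line])
        params[(line, "KINI-D")] = (1.2, 1.0, _FIXTURE_KINI_ED50[line])
    return params


def make_fixture_bundle(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write a small ready-to-run screen dataset with known ground truth.

    Six cell lines (including an HR-defective hypersensitive analogue
    and its resistant revertant), three PARPi-like drugs with shared
    per-line potency plus one kinase-inhibitor-like control drug, three
    replicates, low read noise. Writes reads/layout/library/annotations
    CSVs and a truth JSON; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = ScreenSimConfig(
        n_cell_lines=len(FIXTURE_CELL_LINES),
        n_drugs=len(FIXTURE_DRUGS),
        noise_sigma=0.05,
        seed=seed,
    )
    params = _fixture_params()
    rng = np.random.default_rng(seed)
    targets = {d: "PARP" for d in FIXTURE_PARPI}
    targets["KINI-D"] = "kinase"
    datasets = _simulate_from_params(
        rng, cfg, params, FIXTURE_CELL_LINES, FIXTURE_DRUGS, targets
    )
    c_min, c_max = cfg.dose_series[0], cfg.dose_series[-1]
    flags = {
        line: {
            "BRCA1_status": (
                "mutant" if line == "OS-HRD"
                else "revertant" if line == "OS-HRD-REV"
                else "wild-type"
            ),
            "HR_status": "defective" if line == "OS-HRD" else "proficient",
        }
        for line in FIXTURE_CELL_LINES
    }
    annotations = [
        CellLineAnnotation(line, "osteosarcoma", flags[line])
        for line in FIXTURE_CELL_LINES
    ]
    paths = {
        "reads": out_dir / "reads.csv",
        "layout": out_dir / "layout.csv",
        "library": out_dir / "library.csv",
        "annotations": out_dir / "annotations.csv",
        "truth": out_dir / "truth.json",
    }
    write_screen_datasets(datasets, paths["reads"])
    layouts = {
        pid: layout
        for ds in datasets.values()
        for rep in ds.replicates
        for pid, layout in rep.layouts.items()
    }
    write_layouts(layouts, paths["layout"])
    write_library(next(iter(datasets.values())).library, paths["library"])
    write_annotations(annotations, paths["annotations"])
    truth_doc = {
        "seed": seed,
        "noise_sigma": cfg.noise_sigma,
        "dose_series": list(cfg.dose_series),
        "cell_lines": list(FIXTURE_CELL_LINES),
        "drugs": list(FIXTURE_DRUGS),
        "parpi_drugs": list(FIXTURE_PARPI),
        "params": {
            f"{line}|{drug}": list(params[(line, drug)])
            for (line, drug) in sorted(params)
        },
        "auc_unscaled": {
            f"{line}|{drug}": true_auc_unscaled(*params[(line, drug)], c_min, c_max)
            for (line, drug) in sorted(params)
        },
        "auc_scaled": {
            f"{line}|{drug}": true_auc_scaled(*params[(line, drug)], c_min, c_max)
            for (line, drug) in sorted(params)
        },
        "genotype_flags": flags,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths
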