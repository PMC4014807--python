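"""Seeded synthetic screens with planted ground truth.

The generator emulates the arrayed-screen workflow the analysis modules
are built for: 384-well library plates with control wells in fixed outer
columns (a strong positive such as STX16, intermediate positives CLTC and
KDELR1, a cell-death control PLK1 and a GFP negative), sample wells that
each target one gene, replicate readout columns, and the systematic
artifacts that motivate the normalizations — per-plate baseline drift and
row/column offset surfaces. Planted hit genes, per-reagent potencies,
enriched GO terms and PPI cliques give every downstream stage a known
truth to recover.

Default scales mimic a control-normalized luminescence readout: samples at
baseline 0 with SD 0.1, the negative control at 0 and the strong positive
at 1 with SD 0.05, and planted hits shifted by 5 sample-SDs — the strength
of a solid trafficking regulator in a toxin-resistance assay, comfortably
above but of the same order as a 2-3 SD hit threshold.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationStore
from .data_model import SAMPLE, SCHEMA_COLUMNS, ScreenTable
from .geometry import GEOMETRY_384, PlateGeometry

__all__ = [
    "SyntheticScreenSpec",
    "GroundTruth",
    "default_control_layout",
    "generate_screen",
    "generate_deconvolution",
    "generate_annotations",
]

#: (mean, SD) of each default control type on the normalized readout scale.
DEFAULT_CONTROLS = {
    "STX16": (1.0, 0.05),
    "CLTC": (0.6, 0.05),
    "KDELR1": (0.5, 0.05),
    "PLK1": (0.1, 0.05),
    "GFP": (0.0, 0.05),
}
#: First synthetic Entrez id; well above the real id range to avoid confusion.
SYNTHETIC_ID_BASE = 9_000_001


def default_control_layout(
    geometry: PlateGeometry = GEOMETRY_384,
    control_types: Sequence[str] = tuple(DEFAULT_CONTROLS),
) -> dict[str, str]:
    """Controls in the first and last plate columns, cycling down the rows.

    Mimics pre-printed library plates that reserve the outer columns for
    controls.
    """
    layout: dict[str, str] = {}
    types = list(control_types)
    k = 0
    for col in (0, geometry.n_cols - 1):
        for row in range(geometry.n_rows):
            layout[geometry.format_well(row, col)] = types[k % len(types)]
            k += 1
    return layout


@dataclass
class SyntheticScreenSpec:
    """Parameters of a synthetic arrayed screen.

    Effects and potencies are in units of ``sample_sd``; artifact and
    drift amplitudes are on the readout scale (a surface value is drawn
    uniformly in +/- amplitude).
    """

    n_plates: int = 4
    geometry: PlateGeometry = GEOMETRY_384
    controls: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROLS)
    )
    control_layout: dict[str, str] | None = None  # well -> control type
    sample_mean: float = 0.0
    sample_sd: float = 0.1
    noise_sd: float | None = None  # well noise SD; defaults to sample_sd
    n_hits: int = 20
    hit_effect: float = 5.0  # shift of planted hits, in sample-SD units
    effect_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    row_artifact: float = 0.0
    col_artifact: float = 0.0
    plate_drift: float = 0.0
    n_replicates: int = 2
    column_basename: str = "Signal"
    reagents_per_gene: int = 4
    potencies: Sequence[float] | None = None  # explicit per-reagent potencies
    potency_range: tuple[float, float] = (0.3, 1.0)
    n_deconv_genes: int = 200

    def __post_init__(self) -> None:
        if self.sample_sd <= 0:
            raise ValueError("sample_sd must be > 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (_, sd) in self.controls.items():
            if sd < 0:
                raise ValueError(f"control {name!r} has negative SD")
        if not np.isfinite(self.hit_effect):
            raise ValueError("hit effect must be finite")
        layout = self.control_layout
        if layout is None:
            layout = default_control_layout(self.geometry, tuple(self.controls))
            self.control_layout = layout
        for well, ctype in layout.items():
            self.geometry.parse_well(well)  # raises if outside geometry
            if ctype not in self.controls:
                raise ValueError(f"layout names undeclared control {ctype!r}")

    @property
    def well_noise_sd(self) -> float:
        return self.sample_sd if self.noise_sd is None else self.noise_sd

    @property
    def control_types(self) -> tuple[str, ...]:
        return tuple(self.controls)

    @property
    def sample_wells_per_plate(self) -> int:
        return self.geometry.n_wells - len(self.control_layout)

    @property
    def n_genes(self) -> int:
        return self.n_plates * self.sample_wells_per_plate

    def data_columns(self) -> list[str]:
        if self.n_replicates == 1:
            return [self.column_basename]
        return [f"{self.column_basename}_rep{r + 1}" for r in range(self.n_replicates)]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic table."""

    gene_effects: dict[int, float] = field(default_factory=dict)  # SD units, all genes
    hit_genes: dict[int, float] = field(default_factory=dict)  # non-zero effects only
    artifact_surfaces: dict[tuple[int, str], tuple[np.ndarray, np.ndarray, float]] = field(
        default_factory=dict
    )  # (plate, column) -> (row offsets, col offsets, drift)
    reagent_potency: dict[str, float] = field(default_factory=dict)
    planted_terms: list[tuple[str, str, float, frozenset[int]]] = field(
        default_factory=list
    )  # (term, namespace, fold, target genes)
    planted_cliques: list[tuple[int, ...]] = field(default_factory=list)


def _gene_ids(n: int) -> tuple[list[int], list[str]]:
    ids = [SYNTHETIC_ID_BASE + i for i in range(n)]
    symbols = [f"SYN{i + 1:05d}" for i in range(n)]
    return ids, symbols


def _draw_effects(spec: SyntheticScreenSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_genes
    if spec.effect_sampler is not None:
        effects = np.asarray(spec.effect_sampler(rng, n), dtype=float)
        if effects.shape != (n,):
            raise ValueError("effect_sampler must return one effect per gene")
        return effects
    if spec.n_hits > n:
        raise ValueError("more planted hits than sample wells")
    effects = np.zeros(n)
    hit_idx = rng.choice(n, size=spec.n_hits, replace=False)
    effects[hit_idx] = spec.hit_effect
    return effects


def generate_screen(
    spec: SyntheticScreenSpec, seed: int
) -> tuple[ScreenTable, GroundTruth]:
    """Generate one pooled primary screen and its ground truth.

    Sample wells read ``sample_mean + effect * sample_sd + artifacts +
    noise``; control wells read their own (mean, SD) plus the same plate
    artifacts. Replicate columns share the gene effects but get
    independent artifact surfaces and noise, as separate physical plates
    would. Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    geom = spec.geometry
    effects = _draw_effects(spec, rng)
    gene_ids, gene_symbols = _gene_ids(spec.n_genes)
    truth = GroundTruth(
        gene_effects=dict(zip(gene_ids, effects.tolist())),
        hit_genes={g: e for g, e in zip(gene_ids, effects.tolist()) if e != 0.0},
    )
    layout = spec.control_layout
    sample_labels = [w for w in geom.all_wells() if w not in layout]
    sample_pos = {w: k for k, w in enumerate(sample_labels)}

    rows: list[dict] = []
    gene_cursor = 0
    for plate in range(1, spec.n_plates + 1):
        plate_rows: list[dict] = []
        for well in geom.all_wells():
            if well in layout:
                ctype = layout[well]
                plate_rows.append(
                    {
                        "plate": plate,
                        "well": well,
                        "well_type": ctype,
                        "gene_symbol": ctype,
                        "entrez_id": pd.NA,
                        "reagent_id": pd.NA,
                    }
                )
            else:
                g = gene_cursor + sample_pos[well]
                plate_rows.append(
                    {
                        "plate": plate,
                        "well": well,
                        "well_type": SAMPLE,
                        "gene_symbol": gene_symbols[g],
                        "entrez_id": gene_ids[g],
                        "reagent_id": pd.NA,
                    }
                )
        gene_cursor += len(sample_labels)
        rows.extend(plate_rows)

    df = pd.DataFrame(rows)
    df["entrez_id"] = pd.array(
        [None if v is pd.NA else int(v) for v in df["entrez_id"]], dtype="Int64"
    )
    for col_name in spec.data_columns():
        values = np.empty(len(df))
        for plate in range(1, spec.n_plates + 1):
            row_off = rng.uniform(-spec.row_artifact, spec.row_artifact, geom.n_rows) if spec.row_artifact else np.zeros(geom.n_rows)
            col_off = rng.uniform(-spec.col_artifact, spec.col_artifact, geom.n_cols) if spec.col_artifact else np.zeros(geom.n_cols)
            drift = float(rng.uniform(-spec.plate_drift, spec.plate_drift)) if spec.plate_drift else 0.0
            truth.artifact_surfaces[(plate, col_name)] = (row_off, col_off, drift)
            mask = (df["plate"] == plate).to_numpy()
            sub = df.loc[mask]
            vals = np.empty(mask.sum())
            for k, (well, wtype, gid) in enumerate(
                zip(sub["well"], sub["well_type"], sub["entrez_id"])
            ):
                i, j = geom.parse_well(well)
                surface = row_off[i] + col_off[j] + drift
                if wtype == SAMPLE:
                    eff = truth.gene_effects[int(gid)]
                    base = spec.sample_mean + eff * spec.sample_sd
                    noise = rng.normal(0.0, spec.well_noise_sd) if spec.well_noise_sd > 0 else 0.0
                else:
                    mean, sd = spec.controls[wtype]
                    base = mean
                    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                vals[k] = base + surface + noise
            values[mask] = vals
        df[col_name] = values

    table = ScreenTable(
        records=df[SCHEMA_COLUMNS + spec.data_columns()],
        data_columns=spec.data_columns(),
        name=f"synthetic_screen_seed{seed}",
        nature="raw",
        geometry=geom,
        control_types=spec.control_types,
    )
    return table, truth


def generate_deconvolution(
    spec: SyntheticScreenSpec, seed: int
) -> tuple[ScreenTable, GroundTruth]:
    """Generate a deconvolution (multi-reagent validation) screen.

    One row per (gene, reagent): ``n_deconv_genes`` genes, each re-tested
    with ``reagents_per_gene`` individual reagents whose score is
    ``gene effect x reagent potency + noise``. Potencies come from the
    explicit ``potencies`` sequence (cycled per gene) or are drawn
    uniformly from ``potency_range`` — individual siRNAs tend to be less
    potent than the pool that nominated the gene.
    """
    if spec.reagents_per_gene < 2:
        raise ValueError("deconvolution needs >= 2 reagents per gene")
    rng = np.random.default_rng(seed)
    geom = spec.geometry
    n_genes = spec.n_deconv_genes
    gene_ids, gene_symbols = _gene_ids(n_genes)
    effect_value = spec.hit_effect * spec.sample_sd

    truth = GroundTruth(
        gene_effects={g: spec.hit_effect for g in gene_ids},
        hit_genes={g: spec.hit_effect for g in gene_ids},
    )
    layout = spec.control_layout
    sample_labels = [w for w in geom.all_wells() if w not in layout]

    rows: list[dict] = []
    serial = 0
    for g in range(n_genes):
        if spec.potencies is not None:
            pots = [float(spec.potencies[r % len(spec.potencies)]) for r in range(spec.reagents_per_gene)]
        else:
            pots = rng.uniform(*spec.potency_range, spec.reagents_per_gene).tolist()
        for r in range(spec.reagents_per_gene):
            reagent = f"R{g + 1:05d}.{r + 1}"
            truth.reagent_potency[reagent] = pots[r]
            plate = serial // len(sample_labels) + 1
            well = sample_labels[serial % len(sample_labels)]
            serial += 1
            noise = rng.normal(0.0, spec.well_noise_sd) if spec.well_noise_sd > 0 else 0.0
            rows.append(
                {
                    "plate": plate,
                    "well": well,
                    "well_type": SAMPLE,
                    "gene_symbol": gene_symbols[g],
                    "entrez_id": gene_ids[g],
                    "reagent_id": reagent,
                    spec.column_basename: spec.sample_mean + effect_value * pots[r] + noise,
                }
            )
    df = pd.DataFrame(rows)
    df["entrez_id"] = pd.array(df["entrez_id"], dtype="Int64")
    table = ScreenTable(
        records=df[SCHEMA_COLUMNS + [spec.column_basename]],
        data_columns=[spec.column_basename],
        name=f"synthetic_deconvolution_seed{seed}",
        nature="raw",
        geometry=geom,
        control_types=spec.control_types,
    )
    return table, truth


def generate_annotations(
    genes: Iterable[int],
    n_terms: int = 50,
    planted: Sequence[tuple[str, str, float, Iterable[int]]] = (),
    ppi_density: float = 0.0,
    planted_cliques: Sequence[Iterable[int]] = (),
    seed: int = 0,
    background_prob: float = 0.05,
    genome_size: int = 22_000,
) -> tuple[AnnotationStore, GroundTruth]:
    """Generate a GO/PPI store with planted enrichment and cliques.

    Background terms annotate each gene independently with probability
    ``background_prob``. Each planted entry ``(term, namespace, fold,
    target_genes)`` annotates its targets with probability ``fold x
    background_prob`` (capped at 1) and everyone else at background rate.
    Background PPI edges are Bernoulli(``ppi_density``) over all gene
    pairs; planted cliques are fully connected.
    """
    genes = [int(g) for g in genes]
    rng = np.random.default_rng(seed)
    store = AnnotationStore(genome_size=genome_size)
    namespaces = ("BP", "CC", "MF")
    for t in range(n_terms):
        ns = namespaces[t % 3]
        go_id, term = f"GO:SYN{t + 1:04d}", f"synthetic {ns} term {t + 1}"
        hit = rng.random(len(genes)) < background_prob
        for g, h in zip(genes, hit):
            if h:
                store.add_annotation(g, go_id, term, ns)
    truth = GroundTruth()
    for k, (term, ns, fold, targets) in enumerate(planted):
        if fold < 1:
            raise ValueError("planted fold-enrichment must be >= 1")
        targets = {int(g) for g in targets}
        if not targets <= set(genes):
            raise ValueError("planted target genes must be part of the gene universe")
        go_id = f"GO:PLANT{k + 1:03d}"
        p_target = min(1.0, fold * background_prob)
        for g in genes:
            p = p_target if g in targets else background_prob
            if rng.random() < p:
                store.add_annotation(g, go_id, term, ns)
        truth.planted_terms.append((term, ns, float(fold), frozenset(targets)))
    if ppi_density > 0:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < ppi_density:
                    store.add_edge(genes[i], genes[j])
    for clique in planted_cliques:
        members = tuple(int(g) for g in clique)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                store.add_edge(members[i], members[j])
        truth.planted_cliques.append(members)
    return store, truth
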