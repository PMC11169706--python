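"""Synthetic sagittal-brain MSI phantom with ground truth.

The phantom emulates the statistical structure the discriminant pipeline
assumes, not rat anatomy: a sagittal section is a tissue ellipse on an
embedding background, subdivided into five schematic regions — gray matter
(GM), white matter core (WM), hippocampus (HC), outer cortex (OC, the dorsal
outer shell) and corpus callosum (CC, a dorsal band) — drawn as ellipse/band
shapes and made disjoint by priority assignment (OC > CC > HC > WM > GM).

Every pixel carries a centroided spectrum built from a peak panel:

* the discriminant lipid panel at theoretical adduct m/z, with per-region
  baselines reflecting lipid-class localization (LPC gray-matter-leaning,
  SM/HexCer and PC potassium adducts white-matter-leaning) and
  injured/sham fold changes taken from the reference annotation table;
* decoy lipids with fold change 1 everywhere, including one strong marker
  decoy per region (these give the segmentation its molecular contrast and
  the ROC filter its negatives);
* MALDI matrix peaks present on every pixel (the DAN monomer/dimer ions)
  and embedding-only peaks off tissue.

Peak m/z gets small ppm jitter; intensities get multiplicative log-normal
pixel noise plus a per-section, per-species log-normal biological factor.
All log-normal factors are mean-one (σ²/2 bias correction), so configured
fold changes are exact in expectation for arithmetic means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MSImageDataset, PixelSpectrum, SectionMetadata, write_dataset, write_samples_file
from .masses import ADDUCTS, Formula, adduct_mz, load_lipid_table, load_reference_annotations
from .segmentation import ROIMask

__all__ = [
    "REGIONS",
    "PanelPeak",
    "PhantomConfig",
    "PhantomTruth",
    "default_config",
    "region_masks",
    "generate_section",
    "generate_cohort",
]

REGIONS = ("GM", "WM", "HC", "OC", "CC")
ALL_REGIONS = REGIONS + ("embedding",)

C13_DELTA = 1.00336


@dataclass(frozen=True)
class PanelPeak:
    """One species in the phantom's peak panel."""

    name: str
    mz: float
    base: float  # intensity scale before region/group factors
    levels: dict  # region -> relative level (0 = absent)
    fc: dict = field(default_factory=dict)  # region -> injured/sham fold change
    kind: str = "lipid"  # lipid | decoy | marker | matrix | embedding | isotope

    def expected(self, region: str, group: str) -> float:
        lvl = self.levels.get(region, 0.0)
        f = self.fc.get(region, 1.0) if group == "injured" else 1.0
        return self.base * lvl * f


@dataclass
class PhantomConfig:
    """Geometry, panel and noise model for the synthetic cohort.

    Defaults: a 120x80 pixel grid at 50 µm pitch, 1 ppm mass jitter SD,
    0.15 multiplicative log-normal pixel noise SD, and 0.05 per-section
    biological variability SD.
    """

    ncol: int = 120
    nrow: int = 80
    pitch_um: float = 50.0
    panel: list[PanelPeak] = field(default_factory=list)
    jitter_ppm: float = 1.0
    noise_sd: float = 0.15
    section_rel_sd: float = 0.05
    add_isotopes: bool = False
    mz_range: tuple[float, float] = (147.0, 1500.0)

    def __post_init__(self) -> None:
        if self.jitter_ppm < 0 or self.noise_sd < 0 or self.section_rel_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        for p in self.panel:
            if p.base <= 0:
                raise ValueError(f"panel peak {p.name}: baseline must be positive")
            if any(v < 0 for v in p.levels.values()):
                raise ValueError(f"panel peak {p.name}: levels must be non-negative")
            if any(f <= 0 for f in p.fc.values()):
                raise ValueError(f"panel peak {p.name}: fold changes must be positive")

    def peaks_of_kind(self, *kinds: str) -> list[PanelPeak]:
        return [p for p in self.panel if p.kind in kinds]

    def background_mz(self) -> list[float]:
        """Known matrix and embedding ion m/z (for background feature removal)."""
        return [p.mz for p in self.peaks_of_kind("matrix", "embedding")]

    def marker_mz(self, region: str) -> float:
        for p in self.panel:
            if p.kind == "marker" and p.name == f"marker_{region}":
                return p.mz
        raise KeyError(f"no marker peak for region {region}")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside each section."""

    masks: dict  # region -> ROIMask
    expected: pd.DataFrame  # species x region expected sham/injured abundance
    mz: dict  # species name -> theoretical m/z


# ---------------------------------------------------------------------------
# geometry

def region_masks(config: PhantomConfig) -> dict:
    """Disjoint region masks on the grid (priority OC > CC > HC > WM > GM)."""
    nrow, ncol = config.nrow, config.ncol
    ys, xs = np.mgrid[0:nrow, 0:ncol]
    cx, cy = ncol * 0.5, nrow * 0.525
    ax, ay = ncol * 0.43, nrow * 0.40
    r = np.sqrt(((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2)
    tissue = r <= 1.0
    dorsal = ys < cy
    oc = tissue & dorsal & (r >= 0.82)
    cc = tissue & dorsal & (r >= 0.55) & (r <= 0.68) & ~oc
    hx, hy = cx + ncol * 0.16, cy - nrow * 0.14
    hc = (
        (((xs - hx) / (ncol * 0.085)) ** 2 + ((ys - hy) / (nrow * 0.075)) ** 2 <= 1.0)
        & tissue & ~oc & ~cc
    )
    wm = tissue & (r <= 0.42) & ~hc & ~cc & ~oc
    gm = tissue & ~oc & ~cc & ~hc & ~wm
    emb = ~tissue
    masks = {"OC": oc, "CC": cc, "HC": hc, "WM": wm, "GM": gm, "embedding": emb}
    return {name: ROIMask(name, m) for name, m in masks.items()}


# ---------------------------------------------------------------------------
# default panel

_CLASS_LEVELS = {
    "LPC": {"GM": 1.3, "OC": 1.4, "HC": 1.2, "WM": 0.6, "CC": 0.6},
    "LPC-O": {"GM": 1.3, "OC": 1.4, "HC": 1.2, "WM": 0.6, "CC": 0.6},
    "PC": {"GM": 1.1, "OC": 1.0, "HC": 1.0, "WM": 0.9, "CC": 0.9},
    "PC+K": {"GM": 0.9, "OC": 0.8, "HC": 0.8, "WM": 1.3, "CC": 1.4},
    "SM": {"GM": 0.6, "OC": 0.5, "HC": 0.7, "WM": 1.5, "CC": 1.6},
    "HexCer": {"GM": 0.6, "OC": 0.5, "HC": 0.7, "WM": 1.5, "CC": 1.6},
}

_DAN = Formula.parse("C10H10N2")
_DAN_DIMER = Formula.parse("C20H18N4")
_DAN_2M = Formula.parse("C20H20N4")


def _lipid_peaks(n_decoys: int) -> list[PanelPeak]:
    lipids = {e.name: e for e in load_lipid_table()}
    ref = load_reference_annotations()
    peaks: list[PanelPeak] = []
    for i, row in ref.iterrows():
        entry = lipids[row["name"]]
        mz = adduct_mz(entry.formula, ADDUCTS[row["adduct"]])
        cls = entry.lipid_class
        if row["adduct"] == "[M+K]+" and cls == "PC":
            cls = "PC+K"
        levels = dict(_CLASS_LEVELS[cls])
        fc = {
            reg: (row[f"fc_{reg}"] if np.isfinite(row[f"fc_{reg}"]) else 1.0)
            for reg in REGIONS
        }
        base = 25.0 + 2.0 * (i % 8)
        peaks.append(
            PanelPeak(
                name=f"{row['name']} {row['adduct']}",
                mz=mz, base=base, levels=levels, fc=fc, kind="lipid",
            )
        )
    # markers: one strong region-specific decoy per region
    existing = [p.mz for p in peaks]
    marker_mz = {"GM": 433.31, "WM": 561.42, "HC": 617.47, "OC": 673.51, "CC": 729.55}
    for reg, mz in marker_mz.items():
        mz = _clear_of(mz, existing)
        existing.append(mz)
        levels = {r: 0.3 for r in REGIONS}
        levels[reg] = 3.0
        peaks.append(PanelPeak(f"marker_{reg}", mz, 80.0, levels, {}, "marker"))
    # decoys with fold change 1 everywhere
    for i in range(n_decoys):
        mz = _clear_of(415.0 + 20.3 * i + 1.7 * (i % 5), existing)
        existing.append(mz)
        # five-phase cycle: every pair of regions differs on most decoys,
        # giving each region a distinct molecular profile
        levels = {
            reg: 0.6 + 0.2 * ((i + j) % 5)
            for j, reg in enumerate(REGIONS)
        }
        base = 60.0 + 1.6 * (i % 50)
        peaks.append(PanelPeak(f"decoy_{i:02d}", mz, base, levels, {}, "decoy"))
    return peaks


def _clear_of(mz: float, existing: list[float], min_ppm: float = 60.0) -> float:
    """Nudge a candidate m/z until it is min_ppm clear of existing peaks and
    of their 13C satellites."""
    guard = [m for e in existing for m in (e, e + C13_DELTA)]
    while any(abs(mz - g) <= mz * min_ppm * 1e-6 for g in guard):
        mz += 0.05
    return mz


def _matrix_peaks() -> list[PanelPeak]:
    everywhere = {r: 1.0 for r in ALL_REGIONS}
    return [
        PanelPeak("DAN [M+H]+", adduct_mz(_DAN, ADDUCTS["[M+H]+"]), 180.0, dict(everywhere), {}, "matrix"),
        PanelPeak("DAN dimer [2M-H2]+.", adduct_mz(_DAN_DIMER, ADDUCTS["[M]+."]), 260.0, dict(everywhere), {}, "matrix"),
        PanelPeak("DAN [2M+H]+", adduct_mz(_DAN_2M, ADDUCTS["[M+H]+"]), 120.0, dict(everywhere), {}, "matrix"),
    ]


def _embedding_peaks() -> list[PanelPeak]:
    emb_only = {"embedding": 1.0}
    return [
        PanelPeak("embedding_a", 365.1312, 220.0, dict(emb_only), {}, "embedding"),
        PanelPeak("embedding_b", 527.2093, 160.0, dict(emb_only), {}, "embedding"),
        PanelPeak("embedding_c", 689.3281, 120.0, dict(emb_only), {}, "embedding"),
    ]


def default_config(
    n_decoys: int = 50,
    add_isotopes: bool = False,
    **overrides,
) -> PhantomConfig:
    """The study-condition phantom: 17-lipid discriminant panel with the
    reference fold changes, 50 decoys (5 of them region markers), matrix and
    embedding ions."""
    panel = _lipid_peaks(n_decoys) + _matrix_peaks() + _embedding_peaks()
    if add_isotopes:
        sats = [
            PanelPeak(
                name=p.name + " +13C",
                mz=p.mz + C13_DELTA,
                base=p.base * 0.45,
                levels=dict(p.levels),
                fc=dict(p.fc),
                kind="isotope",
            )
            for p in panel
            if p.kind in ("lipid", "marker", "decoy")
        ]
        panel = panel + sats
    panel.sort(key=lambda p: p.mz)
    return PhantomConfig(panel=panel, add_isotopes=add_isotopes, **overrides)


def noise_only_config(**overrides) -> PhantomConfig:
    """Same panel but every fold change forced to 1 (pure null)."""
    cfg = default_config(**overrides)
    panel = [
        PanelPeak(p.name, p.mz, p.base, dict(p.levels), {}, p.kind) for p in cfg.panel
    ]
    return PhantomConfig(
        ncol=cfg.ncol, nrow=cfg.nrow, pitch_um=cfg.pitch_um, panel=panel,
        jitter_ppm=cfg.jitter_ppm, noise_sd=cfg.noise_sd,
        section_rel_sd=cfg.section_rel_sd, add_isotopes=cfg.add_isotopes,
        mz_range=cfg.mz_range,
    )


# ---------------------------------------------------------------------------
# generation

def _truth(config: PhantomConfig, masks: dict) -> PhantomTruth:
    rows = []
    for p in config.panel:
        for reg in ALL_REGIONS:
            rows.append(
                {
                    "name": p.name,
                    "kind": p.kind,
                    "region": reg,
                    "expected_sham": p.expected(reg, "sham"),
                    "expected_injured": p.expected(reg, "injured"),
                    "fc": p.fc.get(reg, 1.0),
                }
            )
    return PhantomTruth(
        masks=masks,
        expected=pd.DataFrame(rows),
        mz={p.name: p.mz for p in config.panel},
    )


def generate_section(
    config: PhantomConfig,
    group: str,
    seed,
    metadata: SectionMetadata | None = None,
) -> tuple[MSImageDataset, PhantomTruth]:
    """One synthetic section: dataset plus ground truth.

    Deterministic given (config, group, seed).
    """
    if group not in ("sham", "injured"):
        raise ValueError(f"group must be sham or injured, got {group!r}")
    rng = np.random.default_rng(seed)
    masks = region_masks(config)
    nrow, ncol = config.nrow, config.ncol
    region_of = np.empty((nrow, ncol), dtype=object)
    for name, m in masks.items():
        region_of[m.mask] = name

    peaks = config.panel
    n_peaks = len(peaks)
    mz0 = np.array([p.mz for p in peaks])
    # expected intensity per region x peak
    exp_by_region = {
        reg: np.array([p.expected(reg, group) for p in peaks]) for reg in ALL_REGIONS
    }
    # mean-one log-normal factors
    s_sd = config.section_rel_sd
    section_factor = np.exp(rng.normal(0.0, s_sd, n_peaks) - 0.5 * s_sd**2) if s_sd > 0 else np.ones(n_peaks)

    n_pix = nrow * ncol
    p_sd = config.noise_sd
    pixel_noise = (
        np.exp(rng.normal(0.0, p_sd, (n_pix, n_peaks)) - 0.5 * p_sd**2)
        if p_sd > 0
        else np.ones((n_pix, n_peaks))
    )
    jitter = (
        1.0 + 1e-6 * config.jitter_ppm * rng.normal(0.0, 1.0, (n_pix, n_peaks))
        if config.jitter_ppm > 0
        else np.ones((n_pix, n_peaks))
    )

    spectra: list[PixelSpectrum] = []
    flat = 0
    for row in range(nrow):
        for col in range(ncol):
            reg = region_of[row, col]
            expect = exp_by_region[reg]
            inten = expect * section_factor * pixel_noise[flat]
            mzs = mz0 * jitter[flat]
            flat += 1
            nz = inten > 0
            order = np.argsort(mzs[nz])
            spectra.append(
                PixelSpectrum(mzs[nz][order], inten[nz][order], col + 1, row + 1)
            )
    dataset = MSImageDataset(
        spectra=spectra,
        shape=(nrow, ncol),
        pitch_um=config.pitch_um,
        metadata=metadata,
        mode="processed",
    )
    return dataset, _truth(config, masks)


def generate_cohort(
    config: PhantomConfig,
    n_sham: int = 8,
    n_injured: int = 12,
    master_seed: int = 0,
    outdir: str | Path | None = None,
    sections_per_animal: int = 2,
) -> tuple[list[MSImageDataset], PhantomTruth]:
    """A cohort of sections with per-section seeds spawned from one master
    seed.  Defaults mirror the study design: 8 sham and 12 injured sections,
    two serial sections per animal.

    With ``outdir`` set, writes imzML/ibd pairs, the samples file, truth
    masks (PNG) and the truth table (TSV).
    """
    if n_sham < 1 or n_injured < 1:
        raise ValueError("need at least one section per group")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_sham + n_injured)
    datasets: list[MSImageDataset] = []
    metas: list[SectionMetadata] = []
    truth: PhantomTruth | None = None
    labels = ["sham"] * n_sham + ["injured"] * n_injured
    counters = {"sham": 0, "injured": 0}
    for i, (group, child) in enumerate(zip(labels, children)):
        idx = counters[group]
        counters[group] += 1
        meta = SectionMetadata(
            section_id=f"{group}_s{idx:02d}",
            animal_id=f"{group}_a{idx // sections_per_animal:02d}",
            group=group,
        )
        ds, truth = generate_section(config, group, child, metadata=meta)
        datasets.append(ds)
        metas.append(meta)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            write_dataset(ds, outdir / f"{ds.metadata.section_id}.imzML")
        write_samples_file(metas, outdir / "samples.tsv")
        truth.expected.to_csv(outdir / "truth_table.tsv", sep="\t", index=False)
        for name, mask in truth.masks.items():
            mask.write_png(outdir / f"truth_{name}.png")
    return datasets, truth
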