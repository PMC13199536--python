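"""Reproducibility study synthesis: vertebrae, scans and operator masks.

A study mirrors the design of an intra-/inter-operator segmentation
reproducibility experiment: for every vertebra, Operator-1 contributes three
independent repeat segmentations (intra-operator set) and Operators 2 and 3
one segmentation each; the inter-operator set is Operator-1's first repeat
plus Operators 2 and 3.  Each vertebra also gets one rendered QCT volume
with the five-rod calibration phantom in frame.

Randomness
----------
Everything flows from one master integer seed through
``numpy.random.SeedSequence(master, spawn_key=key)`` with documented keys:

===========================  =======================================
key                          purpose
===========================  =======================================
``(v, 0)``                   vertebra geometry + lesion draw
``(v, 1)``                   scanner noise for the QCT render
``(v, 10*operator+repeat)``  operator mask (operator 1-3, repeat 1-3)
===========================  =======================================

so any single artefact is regenerable in isolation from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .image import QCTImage, SegmentationMask
from .imaging import ScannerModel, render_qct
from .operators import INTER_PRESET, INTRA_PRESET, OperatorProfile, \
    simulate_operator_mask
from .phantoms import Lesion, PhantomGeometry, VertebraPhantom, \
    make_vertebra_phantom

__all__ = ["StudyVertebra", "StudySet", "make_study"]

#: (operator, repeat) pairs generated per vertebra, in manifest order
MASK_SLOTS = ((1, 1), (1, 2), (1, 3), (2, 1), (3, 1))


def _seed(master: int, key: tuple[int, ...]) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=key)


@dataclass
class StudyVertebra:
    vid: int
    condition: str                      # "C" control | "L" lytic
    phantom: VertebraPhantom
    qct: QCTImage
    masks: dict[tuple[int, int], SegmentationMask]   # keyed (operator, repeat)

    def intra_masks(self) -> list[SegmentationMask]:
        """Operator-1's three repeats."""
        return [self.masks[(1, r)] for r in (1, 2, 3)]

    def inter_masks(self) -> list[SegmentationMask]:
        """One mask per operator (Operator-1's first repeat)."""
        return [self.masks[(1, 1)], self.masks[(2, 1)], self.masks[(3, 1)]]


@dataclass
class StudySet:
    master_seed: int
    vertebrae: list[StudyVertebra]
    manifest: dict = field(default_factory=dict)

    @property
    def n_masks(self) -> int:
        return sum(len(v.masks) for v in self.vertebrae)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for v in self.vertebrae:
            v.qct.save(out / f"v{v.vid:02d}_qct.nii.gz")
            for (op, rep), m in v.masks.items():
                m.save(out / f"v{v.vid:02d}_op{op}_rep{rep}_mask.nii.gz")
        path = out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path


def _draw_geometry(base: PhantomGeometry, rng, size_jitter: float
                   ) -> PhantomGeometry:
    f = lambda: 1.0 + rng.uniform(-size_jitter, size_jitter)
    return replace(base, a=base.a * f(), b=base.b * f(),
                   height=base.height * f())


def _draw_lesions(geom: PhantomGeometry, rng) -> tuple[Lesion, ...]:
    """One or two lytic lesions safely inside the body."""
    n = int(rng.integers(1, 3))
    lesions = []
    for _ in range(n):
        r = rng.uniform(0.15, 0.28) * min(geom.a, geom.b)
        center = (rng.uniform(-0.3, 0.3) * geom.a,
                  rng.uniform(-0.3, 0.3) * geom.b,
                  rng.uniform(-0.2, 0.2) * geom.height)
        radii = (r, r * rng.uniform(0.8, 1.2),
                 min(r * rng.uniform(0.9, 1.5), 0.2 * geom.height))
        lesions.append(Lesion(center=center, radii=radii,
                              multiplier=float(rng.uniform(0.0, 0.3))))
    return tuple(lesions)


def make_study(
    n_control: int = 3,
    n_lytic: int = 3,
    seed: int = 0,
    intra_profile: OperatorProfile = INTRA_PRESET,
    inter_profile: OperatorProfile = INTER_PRESET,
    base_geometry: PhantomGeometry | None = None,
    scanner: ScannerModel | None = None,
    size_jitter: float = 0.10,
    profile_overrides: dict[int, tuple[OperatorProfile, OperatorProfile]] | None = None,
    out_dir=None,
) -> StudySet:
    """Generate a full reproducibility study.

    Parameters
    ----------
    n_control, n_lytic
        Number of radiologically intact and lytic vertebrae.
    intra_profile, inter_profile
        Operator variability presets; Operator-1 repeats use the intra
        preset, Operators 2-3 the inter preset.
    profile_overrides
        Optional per-vertebra ``{vid: (intra, inter)}`` profiles, used e.g.
        to plant a known variability gradient across vertebrae.
    size_jitter
        Fractional spread of per-vertebra body dimensions.

    Returns a :class:`StudySet` with ``n_control + n_lytic`` vertebrae and
    five masks each; deterministic given ``seed``.
    """
    if n_control + n_lytic < 1:
        raise ValueError("study needs at least one vertebra")
    base = base_geometry or PhantomGeometry()
    scanner = scanner or ScannerModel()
    sp = scanner.voxel_mm

    conditions = ["C"] * n_control + ["L"] * n_lytic
    vertebrae: list[StudyVertebra] = []
    records = []
    for vid, cond in enumerate(conditions):
        g_rng = np.random.default_rng(_seed(seed, (vid, 0)))
        geom = _draw_geometry(base, g_rng, size_jitter)
        lesions: tuple[Lesion, ...] = ()
        if cond == "L":
            for _ in range(20):     # containment is re-checked analytically
                try:
                    lesions = _draw_lesions(geom, g_rng)
                    make_vertebra_phantom(geom, lesions, spacing=sp,
                                          rod_zone_mm=scanner.rod_zone_mm,
                                          min_grid_xy_mm=scanner.rod_row_extent + 10)
                    break
                except ValueError:
                    lesions = ()
        phantom = make_vertebra_phantom(
            geom, lesions, spacing=sp, rod_zone_mm=scanner.rod_zone_mm,
            min_grid_xy_mm=scanner.rod_row_extent + 10)
        qct = render_qct(phantom, scanner, seed=_seed(seed, (vid, 1)))

        if profile_overrides and vid in profile_overrides:
            p_intra, p_inter = profile_overrides[vid]
        else:
            p_intra, p_inter = intra_profile, inter_profile

        masks = {}
        for op, rep in MASK_SLOTS:
            prof = p_intra if op == 1 else p_inter
            key = (vid, 10 * op + rep)
            masks[(op, rep)] = simulate_operator_mask(
                phantom, prof, seed=_seed(seed, key))
            records.append({
                "vertebra": vid, "condition": cond, "operator": op,
                "repeat": rep, "spawn_key": list(key),
                "mask_file": f"v{vid:02d}_op{op}_rep{rep}_mask.nii.gz",
            })
        vertebrae.append(StudyVertebra(vid, cond, phantom, qct, masks))

    manifest = {
        "master_seed": int(seed),
        "n_control": n_control,
        "n_lytic": n_lytic,
        "voxel_mm": sp,
        "masks": records,
    }
    study = StudySet(master_seed=int(seed), vertebrae=vertebrae,
                     manifest=manifest)
    if out_dir is not None:
        study.save(out_dir)
    return study
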