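"""Mouse-brain region-of-interest (ROI) atlas constants.

The 32-ROI reduction of the 280-region deformation-based-morphometry
parcellation groups fine anatomical regions into five white-matter tracts,
five brainstem areas, two cerebral nuclei, eighteen cerebral cortical areas
(including fifteen isocortical areas) and two cerebellar divisions.  The
class labels follow the six-way anatomical colour scheme used when plotting
community cartography (isocortex, subcortical, white matter, brainstem,
cerebellum, cerebellar nuclei).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ROI_CLASSES",
    "ROI_NAMES",
    "A_PRIORI_ROIS",
    "DEFAULT_COMMUNITIES",
    "RegionHierarchy",
    "default_hierarchy",
    "read_hierarchy",
    "write_hierarchy",
]

# ROI -> anatomical class.  Insertion order defines the canonical column order.
ROI_CLASSES: dict[str, str] = {
    # brainstem
    "hypothalamus": "brainstem",
    "medulla": "brainstem",
    "midbrain": "brainstem",
    "pons": "brainstem",
    "thalamus": "brainstem",
    # cerebellum
    "cerebellar cortex": "cerebellum",
    "cerebellar nuclei": "cerebellar nuclei",
    # cerebral cortex, non-isocortical
    "cortical subplate": "subcortical",
    "hippocampal formation": "subcortical",
    "olfactory areas": "subcortical",
    # isocortex (15 areas)
    "agranular insular area": "isocortex",
    "anterior cingulate area": "isocortex",
    "auditory areas": "isocortex",
    "ectorhinal area": "isocortex",
    "frontal pole": "isocortex",
    "infralimbic area": "isocortex",
    "orbital area": "isocortex",
    "perirhinal area": "isocortex",
    "posterior parietal association areas": "isocortex",
    "prelimbic area": "isocortex",
    "retrosplenial area": "isocortex",
    "somatomotor areas": "isocortex",
    "somatosensory areas": "isocortex",
    "temporal association areas": "isocortex",
    "visual areas": "isocortex",
    # cerebral nuclei
    "pallidum": "subcortical",
    "striatum": "subcortical",
    # white matter tracts
    "cerebellum related fiber tracts": "white matter",
    "cranial nerves": "white matter",
    "extrapyramidal fiber system": "white matter",
    "lateral forebrain bundle system": "white matter",
    "medial forebrain bundle system": "white matter",
}

ROI_NAMES: tuple[str, ...] = tuple(ROI_CLASSES)

# Age-sensitive regions singled out for focused (a-priori) analysis.
A_PRIORI_ROIS: tuple[str, ...] = (
    "anterior cingulate area",
    "hippocampal formation",
    "orbital area",
)

# Default planted covariance communities for the synthetic cohort: four
# anatomically coherent blocks (isocortex; subcortical grey; brainstem +
# cerebellum; white matter).
DEFAULT_COMMUNITIES: dict[str, int] = {
    roi: {
        "isocortex": 0,
        "subcortical": 1,
        "brainstem": 2,
        "cerebellum": 2,
        "cerebellar nuclei": 2,
        "white matter": 3,
    }[cls]
    for roi, cls in ROI_CLASSES.items()
}


@dataclass(frozen=True)
class RegionHierarchy:
    """Total mapping from fine anatomical regions onto named ROIs.

    Parameters
    ----------
    mapping
        fine-region name -> ROI name; must cover every fine region present
        in a table it is applied to.
    roi_class
        Optional ROI -> anatomical class label.
    """

    mapping: dict[str, str]
    roi_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("hierarchy mapping is empty")
        for roi, cls in self.roi_class.items():
            if roi not in set(self.mapping.values()):
                raise ValueError(f"class label for unknown ROI {roi!r}")

    @property
    def rois(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for roi in self.mapping.values():
            seen.setdefault(roi)
        return tuple(seen)

    def members(self, roi: str) -> tuple[str, ...]:
        return tuple(f for f, r in self.mapping.items() if r == roi)


def default_hierarchy() -> RegionHierarchy:
    """Identity hierarchy over the canonical 32 ROIs (already reduced data)."""
    return RegionHierarchy(
        mapping={roi: roi for roi in ROI_NAMES},
        roi_class=dict(ROI_CLASSES),
    )


def read_hierarchy(path) -> RegionHierarchy:
    """Read a hierarchy from delimited text: fine_region, roi[, roi_class]."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "fine_region" not in cols or "roi" not in cols:
        raise ValueError(f"{path}: expected columns fine_region, roi")
    mapping = dict(zip(df["fine_region"].astype(str), df["roi"].astype(str)))
    roi_class: dict[str, str] = {}
    if "roi_class" in cols:
        for roi, cls in zip(df["roi"], df["roi_class"]):
            if isinstance(cls, str) and cls:
                roi_class[str(roi)] = cls
    return RegionHierarchy(mapping=mapping, roi_class=roi_class)


def write_hierarchy(hierarchy: RegionHierarchy, path) -> None:
    import pandas as pd

    rows = [
        {
            "fine_region": fine,
            "roi": roi,
            "roi_class": hierarchy.roi_class.get(roi, ""),
        }
        for fine, roi in hierarchy.mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
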