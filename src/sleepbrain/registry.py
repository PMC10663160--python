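"""Catalogue of brain measures analysed by the pipeline.

The default registry mirrors a standard whole-brain ROI analysis: the
Desikan-Killiany cortical parcellation (34 regions, summed across
hemispheres) minus the temporal and frontal poles, which are too noisy to
analyse reliably, leaving 32 cortical thickness measures; plus 19
volumetric measures (subcortical structures, white-matter compartments,
corpus callosum segments, ventricles, total grey volume and intracranial
volume).

Each entry carries the metadata the downstream stages need: the metric
(thickness vs volume, which decides whether ICV enters as a covariate),
the FDR family, whether the region enters the meta-analysis and in which
weighting block, and the peak direction (ventricles expand rather than
shrink, so their "peak" is the argmin of the fitted sleep profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = ["Region", "RegionRegistry", "default_registry", "DK_CORTICAL_34", "VOLUMETRIC_19"]


@dataclass(frozen=True)
class Region:
    name: str
    klass: Literal["cortical", "subcortical", "ventricle", "global"]
    metric: Literal["thickness", "volume"]
    fdr_family: str
    meta_include: bool = True
    meta_block: str | None = None  # 'cortical' or 'subcortical' when included
    composite: bool = False        # sums of other regions (TGV) -- never pooled
    direction: Literal["maximize", "minimize"] = "maximize"
    exclude_reason: str | None = None

    @property
    def uses_icv(self) -> bool:
        """ICV is a covariate for volumes only, and never for ICV itself."""
        return self.metric == "volume" and self.name != "ICV"


# Desikan-Killiany parcellation, 34 bilateral regions.
DK_CORTICAL_34 = [
    "bankssts", "caudal anterior cingulate", "caudal middle frontal", "cuneus",
    "entorhinal", "frontal pole", "fusiform", "inferior parietal",
    "inferior temporal", "insula", "isthmus cingulate", "lateral occipital",
    "lateral orbitofrontal", "lingual", "medial orbitofrontal",
    "middle temporal", "paracentral", "parahippocampal", "pars opercularis",
    "pars orbitalis", "pars triangularis", "pericalcarine", "postcentral",
    "posterior cingulate", "precentral", "precuneus",
    "rostral anterior cingulate", "rostral middle frontal", "superior frontal",
    "superior parietal", "superior temporal", "supramarginal", "temporal pole",
    "transverse temporal",
]

_CORTICAL_EXCLUDED = {"temporal pole", "frontal pole"}

# The 19 volumetric measures of the subcortical battery.
# (name, klass, meta_include, composite, direction, exclude_reason)
VOLUMETRIC_19 = [
    ("Accumbens", "subcortical", True, False, "maximize", None),
    ("Amygdala", "subcortical", True, False, "maximize", None),
    ("Brainstem", "subcortical", True, False, "maximize", None),
    ("Caudate", "subcortical", True, False, "maximize", None),
    ("CC anterior", "subcortical", False, False, "maximize", "corpus callosum: peak mostly undefined (monotone profile)"),
    ("CC central", "subcortical", False, False, "maximize", "corpus callosum: peak mostly undefined (monotone profile)"),
    ("CC mid-anterior", "subcortical", False, False, "maximize", "corpus callosum: peak mostly undefined (monotone profile)"),
    ("CC mid-posterior", "subcortical", False, False, "maximize", "corpus callosum: peak mostly undefined (monotone profile)"),
    ("CC posterior", "subcortical", False, False, "maximize", "corpus callosum: peak mostly undefined (monotone profile)"),
    ("Cerebellum cortex", "subcortical", True, False, "maximize", None),
    ("Cerebellum white matter", "subcortical", True, False, "maximize", None),
    ("Cerebral white matter", "subcortical", True, False, "maximize", None),
    ("ICV", "global", False, False, "maximize", "covariate, not an outcome of the meta-analysis"),
    ("Hippocampus", "subcortical", True, False, "maximize", None),
    ("Pallidum", "subcortical", True, False, "maximize", None),
    ("Putamen", "subcortical", True, False, "maximize", None),
    ("Thalamus", "subcortical", True, False, "maximize", None),
    ("TGV", "global", False, True, "maximize", "sum of other included variables"),
    ("Ventricles", "ventricle", True, False, "minimize", None),
]


@dataclass
class RegionRegistry:
    regions: dict[str, Region] = field(default_factory=dict)

    def add(self, region: Region) -> None:
        if region.name in self.regions:
            raise ValueError(f"duplicate region name: {region.name!r}")
        self.regions[region.name] = region

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __iter__(self):
        return iter(self.regions.values())

    def __len__(self) -> int:
        return len(self.regions)

    def names(self) -> list[str]:
        return list(self.regions)

    def cortical(self) -> list[Region]:
        return [r for r in self if r.klass == "cortical"]

    def volumetric(self) -> list[Region]:
        return [r for r in self if r.metric == "volume"]

    def meta_regions(self) -> list[Region]:
        return [r for r in self if r.meta_include and not r.composite]

    def column_name(self, name: str) -> str:
        """Data-frame column for a region (lower snake case)."""
        return name.lower().replace(" ", "_").replace("-", "_")


def default_registry(include_cortical: bool = True,
                     include_volumetric: bool = True) -> RegionRegistry:
    """Build the default 32-cortical + 19-volumetric registry."""
    reg = RegionRegistry()
    if include_cortical:
        for name in DK_CORTICAL_34:
            if name in _CORTICAL_EXCLUDED:
                continue
            reg.add(Region(name=name, klass="cortical", metric="thickness",
                           fdr_family="cortical", meta_block="cortical"))
    if include_volumetric:
        for name, klass, inc, comp, direction, reason in VOLUMETRIC_19:
            reg.add(Region(
                name=name, klass=klass, metric="volume",
                fdr_family="subcortical",
                meta_include=inc, composite=comp, direction=direction,
                meta_block="subcortical" if inc else None,
                exclude_reason=reason,
            ))
    return reg
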