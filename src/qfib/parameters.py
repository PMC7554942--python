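"""The 56-parameter refined collagen-quantification vector.

28 parameters describe the periportal region and 28 the reduced
perisinusoidal (RPS) region.  Per region there are three strata — all
fibers, aggregated (Agg) and distributed (Dis) — each contributing a
collagen area percentage, five fiber counts (#Str, #ShortStr, #LongStr,
#ThinStr, #ThickStr) and three totals (StrArea, StrLength, StrWidth),
plus one per-region intersection count:

    %R %RAgg %RDis
    #StrR #ShortStrR #LongStrR #ThinStrR #ThickStrR
    StrAreaR StrLengthR StrWidthR
    <the 8 count/total parameters again for Agg, then for Dis>
    #IntersectionR

for R in {Periportal, RPS}.  "%R" is the collagen area of the stratum's
fibers as a percentage of the region area (collagen-proportionate-area
convention).  Legacy "PS" spellings (e.g. "#ThickStrPS") alias the
corresponding RPS names.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .morphometry import FiberString, MorphometryConfig
from .regions import RegionSet

__all__ = [
    "SCHEMA_VERSION",
    "parameter_schema",
    "periportal_schema",
    "rps_schema",
    "canonical_name",
    "classify_parameter_name",
    "compute_parameters",
    "aggregate_parameters",
    "ParameterVector",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_REGION_TOKENS = ("Periportal", "RPS")

_COUNT_TOTAL_BLOCK = [
    "#Str{r}{s}",
    "#ShortStr{r}{s}",
    "#LongStr{r}{s}",
    "#ThinStr{r}{s}",
    "#ThickStr{r}{s}",
    "StrArea{r}{s}",
    "StrLength{r}{s}",
    "StrWidth{r}{s}",
]


def _region_schema(region: str) -> list[str]:
    names = [f"%{region}", f"%{region}Agg", f"%{region}Dis"]
    for stratum in ("", "Agg", "Dis"):
        names += [t.format(r=region, s=stratum) for t in _COUNT_TOTAL_BLOCK]
    names.append(f"#Intersection{region}")
    return names


def periportal_schema() -> list[str]:
    """The 28 periportal parameter names, in canonical order."""
    return _region_schema("Periportal")


def rps_schema() -> list[str]:
    """The 28 reduced-perisinusoidal parameter names, in canonical order."""
    return _region_schema("RPS")


def parameter_schema() -> list[str]:
    """All 56 parameter names: periportal block then RPS block."""
    return periportal_schema() + rps_schema()


_SCHEMA = parameter_schema()
_SCHEMA_SET = frozenset(_SCHEMA)

#: legacy "PS" spellings of the RPS names, as printed in older outputs
_ALIASES = {name.replace("RPS", "PS"): name for name in rps_schema()}


def canonical_name(name: str) -> str:
    """Resolve a parameter name or legacy "PS" alias to its canonical form."""
    if name in _SCHEMA_SET:
        return name
    if name in _ALIASES:
        return _ALIASES[name]
    raise KeyError(f"unknown parameter name {name!r}")


def classify_parameter_name(name: str) -> dict[str, str]:
    """Parse a parameter name into (region_family, stratum, metric).

    region_family is "periportal" or "perisinusoidal"; stratum is "all",
    "Agg" or "Dis"; metric is one of percent/count/area/length/width/
    intersection.
    """
    cname = canonical_name(name)
    if "Periportal" in cname:
        family, region_token = "periportal", "Periportal"
    else:
        family, region_token = "perisinusoidal", "RPS"
    tail = cname.split(region_token, 1)[1]
    stratum = tail if tail in ("Agg", "Dis") else "all"
    if cname.startswith("%"):
        metric = "percent"
    elif cname.startswith("#Intersection"):
        metric = "intersection"
    elif cname.startswith("#"):
        metric = "count"
    elif cname.startswith("StrArea"):
        metric = "area"
    elif cname.startswith("StrLength"):
        metric = "length"
    elif cname.startswith("StrWidth"):
        metric = "width"
    else:  # pragma: no cover - schema is closed
        raise KeyError(f"unparseable parameter name {name!r}")
    return {"region_family": family, "stratum": stratum, "metric": metric}


@dataclass
class ParameterVector:
    """The 56 named parameter values for one sample."""

    sample_id: str
    values: dict[str, float]
    thresholds_used: MorphometryConfig = field(default_factory=MorphometryConfig)

    def __post_init__(self) -> None:
        if list(self.values.keys()) != _SCHEMA:
            raise ValueError("values must carry exactly the 56-name schema in order")

    def __getitem__(self, name: str) -> float:
        return self.values[canonical_name(name)]

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "schema_version": SCHEMA_VERSION,
            "thresholds": {
                "long_length_um": self.thresholds_used.long_length_um,
                "thick_width_um": self.thresholds_used.thick_width_um,
                "aggregated_component_area_um2": self.thresholds_used.aggregated_component_area_um2,
                "intersection_merge_radius_um": self.thresholds_used.intersection_merge_radius_um,
            },
            "values": dict(self.values),
        }


def _stratum_fibers(fibers: list[FiberString], stratum: str) -> list[FiberString]:
    if stratum == "Agg":
        return [f for f in fibers if f.is_aggregated]
    if stratum == "Dis":
        return [f for f in fibers if not f.is_aggregated]
    return fibers


def aggregate_parameters(
    fibers: list[FiberString],
    region_areas_um2: dict[str, float],
    intersections: dict[str, int],
    sample_id: str = "",
    thresholds: MorphometryConfig | None = None,
) -> ParameterVector:
    """Aggregate measured fibers into the 56-parameter vector.

    ``region_areas_um2`` maps "periportal"/"rps" to the region's physical
    area; ``intersections`` maps the same keys to intersection counts.
    Portal-region fibers contribute to no parameter.  A region of zero
    area with fibers in it yields 0 for its percentages and logs a
    warning.
    """
    thresholds = thresholds or MorphometryConfig()
    for f in fibers:
        if f.region not in ("portal", "periportal", "rps"):
            raise ValueError(f"fiber {f.fiber_id} has unknown region {f.region!r}")
    values: dict[str, float] = {}
    for region_token, region_key in (("Periportal", "periportal"), ("RPS", "rps")):
        in_region = [f for f in fibers if f.region == region_key]
        region_area = float(region_areas_um2.get(region_key, 0.0))
        if region_area <= 0 and in_region:
            logger.warning(
                "region %s has zero area but %d fibers; percentages set to 0",
                region_key, len(in_region),
            )
        for stratum in ("", "Agg", "Dis"):
            sub = _stratum_fibers(in_region, stratum or "all")
            # fsum keeps totals exactly invariant to fiber ordering
            collagen_area = math.fsum(f.area_um2 for f in sub)
            pct = 100.0 * collagen_area / region_area if region_area > 0 else 0.0
            values[f"%{region_token}{stratum}"] = pct
            values[f"#Str{region_token}{stratum}"] = float(len(sub))
            values[f"#ShortStr{region_token}{stratum}"] = float(
                sum(1 for f in sub if not f.is_long))
            values[f"#LongStr{region_token}{stratum}"] = float(
                sum(1 for f in sub if f.is_long))
            values[f"#ThinStr{region_token}{stratum}"] = float(
                sum(1 for f in sub if not f.is_thick))
            values[f"#ThickStr{region_token}{stratum}"] = float(
                sum(1 for f in sub if f.is_thick))
            values[f"StrArea{region_token}{stratum}"] = collagen_area
            values[f"StrLength{region_token}{stratum}"] = math.fsum(
                f.length_um for f in sub)
            values[f"StrWidth{region_token}{stratum}"] = math.fsum(
                f.width_um for f in sub)
        values[f"#Intersection{region_token}"] = float(intersections.get(region_key, 0))
    ordered = {name: values[name] for name in _SCHEMA}
    return ParameterVector(sample_id=sample_id, values=ordered, thresholds_used=thresholds)


def compute_parameters(
    fibers: list[FiberString],
    regions: RegionSet,
    intersections: dict[str, int],
    sample_id: str = "",
    thresholds: MorphometryConfig | None = None,
) -> ParameterVector:
    """Compute the 56-parameter vector for one sample from its regions."""
    areas = {
        "periportal": regions.area_um2("periportal"),
        "rps": regions.area_um2("rps"),
    }
    return aggregate_parameters(
        fibers, areas, intersections, sample_id=sample_id, thresholds=thresholds
    )
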