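"""Motor-coordinate transform and XML instruction files.

Crystal targets live in montage pixel (or µm) coordinates; the stage
moves in mm relative to the direct X-ray beam.  ``StageTransform`` maps
between the two, and ``write_run_xml`` emits the instruction sequence
(move / laser / wait / xray / readout per shot, in route order) that a
stage-and-shutter controller executes.  The XML vocabulary is this
package's own, validated against the bundled schema, and round-trips
losslessly through :func:`parse_run_xml`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .planner import ShotPlan
from .router import Route

__all__ = [
    "StageTransform",
    "Instruction",
    "Timing",
    "px_to_motor",
    "write_run_xml",
    "parse_run_xml",
    "RUN_SCHEMA",
]


@dataclass(frozen=True)
class StageTransform:
    """Pixel-to-motor mapping anchored at the direct-beam position.

    ``axis_signs`` default to (+1, -1): montage rows grow downward while
    the motor y axis points up, matching the chip frame.  ``travel_limit``
    is the maximum |motor coordinate| in mm (±12 mm positioning range
    around the beam).
    """

    beam_center_px: tuple[float, float]  # (x, y) montage pixels
    pixel_scale: float  # µm per pixel
    axis_signs: tuple[int, int] = (1, -1)
    travel_limit_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.travel_limit_mm <= 0:
            raise ValueError("travel limit must be positive")
        if any(s not in (-1, 1) for s in self.axis_signs):
            raise ValueError("axis signs must be ±1")


class TravelLimitError(ValueError):
    """A requested motor position exceeds the stage travel range."""


def px_to_motor(p: tuple[float, float], t: StageTransform) -> tuple[float, float]:
    """Map a montage pixel position to motor mm relative to the beam."""
    x_mm = (p[0] - t.beam_center_px[0]) * t.pixel_scale * t.axis_signs[0] / 1000.0
    y_mm = (p[1] - t.beam_center_px[1]) * t.pixel_scale * t.axis_signs[1] / 1000.0
    if abs(x_mm) > t.travel_limit_mm or abs(y_mm) > t.travel_limit_mm:
        raise TravelLimitError(
            f"target ({x_mm:.3f}, {y_mm:.3f}) mm outside ±{t.travel_limit_mm} mm travel"
        )
    return (x_mm, y_mm)


def um_to_motor(p_um: tuple[float, float], t: StageTransform) -> tuple[float, float]:
    """Map a montage-frame µm position to motor mm."""
    return px_to_motor((p_um[0] / t.pixel_scale, p_um[1] / t.pixel_scale), t)


@dataclass(frozen=True)
class Instruction:
    """One controller instruction; payload fields depend on ``kind``."""

    kind: str  # move | laser | xray | readout | wait
    payload: tuple = ()


@dataclass(frozen=True)
class Timing:
    """Exposure timing: laser pre-illumination, pump-probe delay, X-ray."""

    laser_ms: float = 250.0  # pre-illumination duration
    delay_ms: float = 10.0  # pump-probe delay before the X-ray exposure
    xray_us: float = 1000.0


RUN_SCHEMA = """\
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="run">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="shot" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="move">
                <xs:complexType>
                  <xs:attribute name="x_mm" type="xs:decimal" use="required"/>
                  <xs:attribute name="y_mm" type="xs:decimal" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="laser" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="ms" type="xs:decimal" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="wait" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="ms" type="xs:decimal" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="xray">
                <xs:complexType>
                  <xs:attribute name="us" type="xs:decimal" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="readout">
                <xs:complexType/>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:integer" use="required"/>
            <xs:attribute name="crystal" type="xs:integer" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
      <xs:attribute name="pump_probe" type="xs:boolean" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
"""


def _schema() -> etree.XMLSchema:
    return etree.XMLSchema(etree.fromstring(RUN_SCHEMA.encode()))


def write_run_xml(
    plan: ShotPlan,
    route: Route | None,
    transform: StageTransform,
    timing: Timing | None = None,
    path: str | Path | None = None,
    validate: bool = True,
) -> etree._Element:
    """Emit the XML instruction sequence for a plan in route order.

    For each shot: ``move``; in pump-probe mode ``laser`` then ``wait``;
    ``xray``; ``readout``.  Any shot outside the travel limits aborts with
    a :class:`TravelLimitError` naming the shot.  ``route=None`` keeps the
    plan's own shot order.
    """
    if timing is None:
        timing = Timing()
    by_id = {s.id: s for s in plan.shots}
    order = route.order if route is not None else [s.id for s in plan.shots]
    root = etree.Element(
        "run", version="1", pump_probe="true" if plan.pump_probe else "false"
    )
    for sid in order:
        shot = by_id[sid]
        try:
            x_mm, y_mm = um_to_motor(shot.center, transform)
        except TravelLimitError as exc:
            raise TravelLimitError(f"shot {sid}: {exc}") from exc
        el = etree.SubElement(
            root, "shot", id=str(shot.id), crystal=str(shot.crystal_id)
        )
        etree.SubElement(el, "move", x_mm=f"{x_mm:.6f}", y_mm=f"{y_mm:.6f}")
        if plan.pump_probe:
            etree.SubElement(el, "laser", ms=f"{timing.laser_ms:g}")
            etree.SubElement(el, "wait", ms=f"{timing.delay_ms:g}")
        etree.SubElement(el, "xray", us=f"{timing.xray_us:g}")
        etree.SubElement(el, "readout")
    if validate:
        _schema().assertValid(root)
    if path is not None:
        Path(path).write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True)
        )
    return root


def parse_run_xml(source: str | Path | etree._Element) -> list[Instruction]:
    """Parse a run document back into a flat instruction sequence."""
    if isinstance(source, etree._Element):
        root = source
    else:
        root = etree.parse(str(source)).getroot()
    _schema().assertValid(root)
    instructions: list[Instruction] = []
    for shot in root.iterfind("shot"):
        for el in shot:
            if el.tag == "move":
                instructions.append(
                    Instruction(
                        "move", (float(el.get("x_mm")), float(el.get("y_mm")))
                    )
                )
            elif el.tag in ("laser", "wait"):
                instructions.append(Instruction(el.tag, (float(el.get("ms")),)))
            elif el.tag == "xray":
                instructions.append(Instruction("xray", (float(el.get("us")),)))
            elif el.tag == "readout":
                instructions.append(Instruction("readout"))
    return instructions
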