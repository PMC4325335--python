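"""Experiment-description-language (EDL) style XML configuration.

A multi-site neurofeedback session is declared in a single XML document:
scanner sites, file-based exchange channels (a transmitting OUTPUTMODULE and a
receiving RECEIVEMODULE per site, each with trigger scan indices), the
visualization/scaling module, and the randomised block schedule.  Only one
element of the original schema is documented publicly (the OUTPUTMODULE
fragment); the rest of the schema mirrors it minimally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from xml.etree import ElementTree as ET

logger = logging.getLogger(__name__)

__all__ = [
    "SiteConfig",
    "OutputChannelSpec",
    "ReceiveChannelSpec",
    "VirtObject",
    "VisualizationSpec",
    "ScheduleParams",
    "ExperimentConfig",
    "EDLError",
    "EDLParseError",
    "EDLValidationError",
    "parse_edl",
    "serialize_edl",
    "default_config",
    "OUTPUT_PARAM_FLAGS",
    "RECEIVE_PARAM_FLAGS",
]


class EDLError(Exception):
    """Base class for configuration errors."""


class EDLParseError(EDLError):
    """Malformed XML (reports the offending line)."""


class EDLValidationError(EDLError):
    """Well-formed XML that violates the configuration contract."""


# XML attribute flag <-> exchange payload key.  The OUT_* names follow the
# published OUTPUTMODULE fragment; RCV_* mirrors them on the receive side.
OUTPUT_PARAM_FLAGS: dict[str, str] = {
    "OUT_TEMPLATE_ID": "template_id",
    "OUT_TEMPLATE_LABEL": "template_label",
    "OUT_TEMPLATE_ACTLEVEL": "actlevel",
    "OUT_SOURCE_IMG": "source_img",
    "OUT_MONEY_HUMAN": "reward_human",
    "OUT_MONEY_OPPONENT": "reward_opponent",
    "OUT_HUMAN_STEPSIZE": "stepsize",
}
RECEIVE_PARAM_FLAGS: dict[str, str] = {
    k.replace("OUT_", "RCV_", 1): v for k, v in OUTPUT_PARAM_FLAGS.items()
}

_PLACEHOLDER = re.compile(r"\[([A-Za-z_][A-Za-z0-9_]*)\]")


@dataclass(frozen=True)
class SiteConfig:
    """One MR scanner site (TR in seconds, acquisition geometry)."""

    site_id: str
    tr_seconds: float = 2.0
    n_slices: int = 31
    matrix_size: tuple[int, int] = (64, 64)
    field_label: str = "3T"

    def __post_init__(self) -> None:
        if not self.site_id:
            raise EDLValidationError("site_id must be non-empty")
        if self.tr_seconds <= 0:
            raise EDLValidationError("tr_seconds must be positive")
        if self.n_slices < 1:
            raise EDLValidationError("n_slices must be >= 1")
        if min(self.matrix_size) < 8:
            raise EDLValidationError("matrix dimensions must be >= 8")

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.matrix_size[0], self.matrix_size[1], self.n_slices)


@dataclass(frozen=True)
class OutputChannelSpec:
    """A transmitting file channel (one message file on the exchange root)."""

    site_id: str
    state: bool = True
    transport: str = "file"
    write_timestamp: bool = True
    mode: str = "append"
    location: str = ""
    trigger_scans: tuple[int, ...] = (10,)
    output_params: tuple[str, ...] = ("actlevel", "reward_human")

    _param_flags = OUTPUT_PARAM_FLAGS

    def __post_init__(self) -> None:
        if self.transport != "file":
            raise EDLValidationError(f"unsupported transport {self.transport!r}")
        if self.mode not in ("append", "overwrite"):
            raise EDLValidationError(f"unknown channel mode {self.mode!r}")
        if self.state and not self.location:
            raise EDLValidationError(
                f"active channel for site {self.site_id!r} has no LOCATION"
            )
        if any(s < 1 for s in self.trigger_scans):
            raise EDLValidationError("trigger scans are 1-based positive indices")
        known = list(self._param_flags.values())
        unknown = set(self.output_params) - set(known)
        if unknown:
            raise EDLValidationError(f"unknown channel params: {sorted(unknown)}")
        # params are declared as XML attribute flags, so their order is the
        # schema's canonical flag order, not declaration order
        canonical = tuple(k for k in known if k in set(self.output_params))
        object.__setattr__(self, "output_params", canonical)
        if self.state and _PLACEHOLDER.search(self.location):
            raise EDLValidationError(
                f"unresolved placeholder in active channel location {self.location!r}"
            )


@dataclass(frozen=True)
class ReceiveChannelSpec(OutputChannelSpec):
    """Receiving mirror of :class:`OutputChannelSpec` (cwReceiveScan etc.)."""


@dataclass(frozen=True)
class VirtObject:
    object_id: str
    owner_site: str
    visible_to: tuple[str, ...]


@dataclass(frozen=True)
class VisualizationSpec:
    """Virtual objects, schedule reference and per-site calibration scaling."""

    virt_objects: tuple[VirtObject, ...] = ()
    schedule_ref: str = "main"
    scale_max_value: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for site, scale in self.scale_max_value:
            if scale <= 0:
                raise EDLValidationError(
                    f"scaleMaxValue for site {site!r} must be positive"
                )

    def scale_for(self, site_id: str) -> float:
        for site, scale in self.scale_max_value:
            if site == site_id:
                return scale
        return 1.0


@dataclass(frozen=True)
class ScheduleParams:
    """Main-experiment schedule: tasks, runs and the within-block layout."""

    runs_per_task: int = 20
    tasks: tuple[str, ...] = ("single", "cooperation", "competition")
    targets_per_region_per_task: int = 10
    block_layout: tuple[tuple[str, int], ...] = (
        ("baseline", 5),
        ("tapping", 2),
        ("rest", 7),
        ("feedback", 1),
    )

    def __post_init__(self) -> None:
        if self.runs_per_task != 2 * self.targets_per_region_per_task:
            raise EDLValidationError(
                "runs_per_task must equal 2 x targets_per_region_per_task "
                f"(got {self.runs_per_task} vs 2x{self.targets_per_region_per_task})"
            )
        if not self.tasks:
            raise EDLValidationError("at least one task required")
        if any(n < 1 for _, n in self.block_layout):
            raise EDLValidationError("block layout segment counts must be >= 1")

    @property
    def scans_per_block(self) -> int:
        return sum(n for _, n in self.block_layout)


@dataclass(frozen=True)
class ExperimentConfig:
    sites: tuple[SiteConfig, ...]
    output_channels: tuple[OutputChannelSpec, ...] = ()
    receive_channels: tuple[ReceiveChannelSpec, ...] = ()
    visualization: VisualizationSpec = field(default_factory=VisualizationSpec)
    schedule_params: ScheduleParams = field(default_factory=ScheduleParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise EDLValidationError("at least one site required")
        nblock = self.schedule_params.scans_per_block
        for ch in (*self.output_channels, *self.receive_channels):
            bad = [s for s in ch.trigger_scans if s > nblock]
            if bad:
                raise EDLValidationError(
                    f"trigger scans {bad} exceed the {nblock}-scan block"
                )

    def site(self, site_id: str) -> SiteConfig:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


# ---------------------------------------------------------------------------
# parsing


def _flag(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in ("on", "true", "1"):
        return True
    if v in ("off", "false", "0"):
        return False
    raise EDLValidationError(f"{context}: expected ON/OFF, got {value!r}")


def _substitute(location: str, substitutions: dict[str, str] | None) -> str:
    loc = location.replace("\\", "/")
    if substitutions:
        loc = _PLACEHOLDER.sub(
            lambda m: substitutions.get(m.group(1), m.group(0)), loc
        )
    return loc


def _parse_channel(
    elem: ET.Element,
    cls: type[OutputChannelSpec],
    scan_tag: str,
    params_tag: str,
    flag_map: dict[str, str],
    substitutions: dict[str, str] | None,
) -> OutputChannelSpec:
    tag = elem.tag
    state = _flag(elem.get("STATE", "ON"), f"{tag} STATE")
    transport = elem.get("TYPE", "FILE").strip().lower()
    wts = _flag(elem.get("WRITETIMESTAMP", "ON"), f"{tag} WRITETIMESTAMP")
    mode = elem.get("MODE", "APPEND").strip().lower()
    site = elem.get("SITE", "")

    loc_elem = elem.find("LOCATION")
    location = _substitute(loc_elem.text or "", substitutions) if loc_elem is not None else ""
    if state and loc_elem is None:
        raise EDLValidationError(f"active {tag} for site {site!r} is missing LOCATION")

    triggers: list[int] = []
    for ts in elem.findall(scan_tag):
        text = (ts.text or "").strip()
        try:
            triggers.append(int(text))
        except ValueError:
            raise EDLValidationError(
                f"{scan_tag} must be an integer scan index, got {text!r}"
            ) from None

    params: list[str] = []
    p = elem.find(params_tag)
    if p is not None:
        for attr, value in p.attrib.items():
            if attr not in flag_map:
                logger.warning("ignoring unknown %s flag %s", params_tag, attr)
                continue
            if _flag(value, f"{params_tag} {attr}"):
                params.append(flag_map[attr])

    return cls(
        site_id=site,
        state=state,
        transport=transport,
        write_timestamp=wts,
        mode=mode,
        location=location,
        trigger_scans=tuple(triggers),
        output_params=tuple(params),
    )


def _parse_layout(text: str) -> tuple[tuple[str, int], ...]:
    layout = []
    for token in text.split():
        label, _, count = token.partition(":")
        try:
            layout.append((label, int(count)))
        except ValueError:
            raise EDLValidationError(f"bad block layout token {token!r}") from None
    return tuple(layout)


_KNOWN_TOP = {"SITE", "OUTPUTMODULE", "RECEIVEMODULE", "VISUALIZEACTMODULE"}


def parse_edl(
    xml_text: str, substitutions: dict[str, str] | None = None
) -> ExperimentConfig:
    """Parse an EDL XML document into a validated :class:`ExperimentConfig`.

    ``substitutions`` resolves ``[NAME]`` placeholders in channel LOCATION
    strings; an unresolved placeholder in an *active* channel is an error.
    Unknown elements are ignored with a logged warning; ON/OFF attribute
    values are case-insensitive.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise EDLParseError(f"malformed XML at line {line}, column {col}: {exc}") from exc

    if root.tag != "EDL":
        raise EDLValidationError(f"root element must be EDL, got {root.tag!r}")

    sites: list[SiteConfig] = []
    out_channels: list[OutputChannelSpec] = []
    rcv_channels: list[ReceiveChannelSpec] = []
    vis = VisualizationSpec()
    sched = ScheduleParams()
    seed = int(root.get("SEED", "0"))

    for elem in root:
        if elem.tag == "SITE":
            mat = tuple(int(x) for x in elem.get("MATRIX", "64 64").split())
            if len(mat) != 2:
                raise EDLValidationError("MATRIX must hold two integers")
            sites.append(
                SiteConfig(
                    site_id=elem.get("ID", ""),
                    tr_seconds=float(elem.get("TR", "2.0")),
                    n_slices=int(elem.get("NSLICES", "31")),
                    matrix_size=mat,  # type: ignore[arg-type]
                    field_label=elem.get("FIELD", ""),
                )
            )
        elif elem.tag == "OUTPUTMODULE":
            out_channels.append(
                _parse_channel(
                    elem, OutputChannelSpec, "CWOUTPUTSCAN", "OUTPUTPARAMS",
                    OUTPUT_PARAM_FLAGS, substitutions,
                )
            )
        elif elem.tag == "RECEIVEMODULE":
            rcv_channels.append(
                _parse_channel(  # type: ignore[assignment]
                    elem, ReceiveChannelSpec, "CWRECEIVESCAN", "RECEIVEPARAMS",
                    RECEIVE_PARAM_FLAGS, substitutions,
                )
            )
        elif elem.tag == "VISUALIZEACTMODULE":
            objs = tuple(
                VirtObject(
                    object_id=o.get("ID", ""),
                    owner_site=o.get("OWNER", ""),
                    visible_to=tuple(o.get("VISIBLETO", "").split()),
                )
                for o in elem.findall("VIRTOBJECT")
            )
            scales = tuple(
                (s.get("SITE", ""), float((s.text or "1").strip()))
                for s in elem.findall("SCALEMAXVALUE")
            )
            rs = elem.find("RANDSTRUCT")
            if rs is not None:
                layout_elem = rs.find("BLOCKLAYOUT")
                layout = (
                    _parse_layout(layout_elem.text or "")
                    if layout_elem is not None
                    else ScheduleParams().block_layout
                )
                sched = ScheduleParams(
                    runs_per_task=int(rs.get("RUNSPERTASK", "20")),
                    tasks=tuple(rs.get("TASKS", "single cooperation competition").split()),
                    targets_per_region_per_task=int(rs.get("TARGETSPERREGION", "10")),
                    block_layout=layout,
                )
                ref = rs.get("REF")
            else:
                ref = None
            vis = VisualizationSpec(
                virt_objects=objs,
                schedule_ref=ref or "main",
                scale_max_value=scales,
            )
        else:
            logger.warning("ignoring unknown EDL element <%s>", elem.tag)

    return ExperimentConfig(
        sites=tuple(sites),
        output_channels=tuple(out_channels),
        receive_channels=tuple(rcv_channels),
        visualization=vis,
        schedule_params=sched,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization


def _emit_channel(
    root: ET.Element, ch: OutputChannelSpec, tag: str, scan_tag: str, params_tag: str,
    flag_map: dict[str, str],
) -> None:
    e = ET.SubElement(
        root,
        tag,
        {
            "SITE": ch.site_id,
            "STATE": "ON" if ch.state else "OFF",
            "TYPE": ch.transport.upper(),
            "WRITETIMESTAMP": "ON" if ch.write_timestamp else "OFF",
            "MODE": ch.mode.upper(),
        },
    )
    loc = ET.SubElement(e, "LOCATION")
    loc.text = ch.location
    for s in ch.trigger_scans:
        ts = ET.SubElement(e, scan_tag)
        ts.text = str(s)
    enabled = set(ch.output_params)
    ET.SubElement(
        e,
        params_tag,
        {attr: ("ON" if key in enabled else "OFF") for attr, key in flag_map.items()},
    )


def serialize_edl(config: ExperimentConfig) -> str:
    """Emit XML accepted by :func:`parse_edl` (round-trip identity)."""
    root = ET.Element("EDL", {"SEED": str(config.rng_seed)})
    for s in config.sites:
        ET.SubElement(
            root,
            "SITE",
            {
                "ID": s.site_id,
                "TR": repr(s.tr_seconds),
                "NSLICES": str(s.n_slices),
                "MATRIX": f"{s.matrix_size[0]} {s.matrix_size[1]}",
                "FIELD": s.field_label,
            },
        )
    for ch in config.output_channels:
        _emit_channel(root, ch, "OUTPUTMODULE", "CWOUTPUTSCAN", "OUTPUTPARAMS",
                      OUTPUT_PARAM_FLAGS)
    for ch in config.receive_channels:
        _emit_channel(root, ch, "RECEIVEMODULE", "CWRECEIVESCAN", "RECEIVEPARAMS",
                      RECEIVE_PARAM_FLAGS)

    vis = ET.SubElement(root, "VISUALIZEACTMODULE")
    for o in config.visualization.virt_objects:
        ET.SubElement(
            vis,
            "VIRTOBJECT",
            {"ID": o.object_id, "OWNER": o.owner_site, "VISIBLETO": " ".join(o.visible_to)},
        )
    sp = config.schedule_params
    rs = ET.SubElement(
        vis,
        "RANDSTRUCT",
        {
            "REF": config.visualization.schedule_ref,
            "RUNSPERTASK": str(sp.runs_per_task),
            "TASKS": " ".join(sp.tasks),
            "TARGETSPERREGION": str(sp.targets_per_region_per_task),
        },
    )
    layout = ET.SubElement(rs, "BLOCKLAYOUT")
    layout.text = " ".join(f"{label}:{n}" for label, n in sp.block_layout)
    for site, scale in config.visualization.scale_max_value:
        sm = ET.SubElement(vis, "SCALEMAXVALUE", {"SITE": site})
        sm.text = repr(scale)

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=False)


def default_config(
    n_sites: int = 2,
    seed: int = 0,
    matrix_size: tuple[int, int] = (64, 64),
    n_slices: int | None = None,
) -> ExperimentConfig:
    """A runnable two-site default: a 3T site and a 7T site exchanging
    activation level and cumulative reward at block-local scan 10.

    Channel locations are file names relative to the exchange-platform root
    directory (each site transmits on its own file and listens on its
    partner's)."""
    fields = ["3T", "7T"] + ["3T"] * max(0, n_sites - 2)
    slices = [31, 20] + [31] * max(0, n_sites - 2)
    ids = [chr(ord("A") + i) for i in range(n_sites)]
    sites = tuple(
        SiteConfig(
            site_id=ids[i],
            tr_seconds=2.0,
            n_slices=n_slices if n_slices is not None else slices[i],
            matrix_size=matrix_size,
            field_label=fields[i],
        )
        for i in range(n_sites)
    )
    out = tuple(
        OutputChannelSpec(
            site_id=s.site_id,
            location=f"{s.site_id}_out.txt",
            trigger_scans=(10,),
            output_params=("actlevel", "reward_human"),
        )
        for s in sites
    )
    # each site listens on its partner's output file (ring topology)
    rcv = tuple(
        ReceiveChannelSpec(
            site_id=s.site_id,
            location=f"{ids[(i + 1) % n_sites]}_out.txt",
            trigger_scans=(10,),
            output_params=("actlevel", "reward_human"),
        )
        for i, s in enumerate(sites)
    )
    vis = VisualizationSpec(
        virt_objects=tuple(
            VirtObject(f"sphere_{s.site_id}", s.site_id, tuple(ids)) for s in sites
        ),
        schedule_ref="main",
        scale_max_value=tuple((s.site_id, 1.0) for s in sites),
    )
    return ExperimentConfig(
        sites=sites,
        output_channels=out,
        receive_channels=rcv,
        visualization=vis,
        schedule_params=ScheduleParams(),
        rng_seed=seed,
    )


def with_seed(config: ExperimentConfig, seed: int) -> ExperimentConfig:
    return replace(config, rng_seed=seed)
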