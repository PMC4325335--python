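"""Central exchange platform: timestamped append-only text-file messaging.

Each declared channel owns one message file under a shared root directory
(the stand-in for the network drive both scanner sites can reach).  A site
appends one line per transmission — at the configured block-local trigger
scans — carrying its current activation level and cumulative reward; the
partner site polls the file once per scan and parses complete lines after
its cursor.

Line format (tab-separated, UTF-8, ``\\n``-terminated)::

    <ISO-8601 timestamp> <site> <block> <scan> key=value [key=value ...]

Floats are written with six decimals; the timestamp field is omitted when
the channel declares WRITETIMESTAMP=OFF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .edl_config import OutputChannelSpec, ReceiveChannelSpec

__all__ = [
    "ExchangeMessage",
    "ExchangePlatform",
    "ReadResult",
    "ExchangeError",
    "write_message",
    "read_messages",
    "exchange_due",
    "format_message",
    "parse_line",
]


class ExchangeError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExchangeMessage:
    """One transmitted record; payload keys are restricted to the channel's
    configured parameters and keep their configured order."""

    site_id: str
    block_index: int
    scan_index: int  # block-local, 1-based
    payload: tuple[tuple[str, float | int | str], ...]
    timestamp: str | None = None  # ISO-8601


@dataclass
class ExchangePlatform:
    """Directory of per-channel message files."""

    root: str
    _cursors: dict[str, int] = field(default_factory=dict)

    def path_for(self, channel: OutputChannelSpec) -> str:
        if not channel.location:
            raise ExchangeError(f"channel for site {channel.site_id!r} has no location")
        loc = channel.location
        path = loc if os.path.isabs(loc) else os.path.join(self.root, loc)
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        return path


def _format_value(value: float | int | str) -> str:
    if isinstance(value, bool):
        raise ExchangeError("boolean payload values are not supported")
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def _parse_value(text: str) -> float | int | str:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def format_message(msg: ExchangeMessage, write_timestamp: bool = True) -> str:
    fields = []
    if write_timestamp:
        if msg.timestamp is None:
            raise ExchangeError("channel requires a timestamp but message has none")
        fields.append(msg.timestamp)
    fields += [msg.site_id, str(msg.block_index), str(msg.scan_index)]
    fields += [f"{k}={_format_value(v)}" for k, v in msg.payload]
    return "\t".join(fields) + "\n"


def parse_line(line: str, has_timestamp: bool = True) -> ExchangeMessage:
    fields = line.rstrip("\n").split("\t")
    min_fields = 4 if has_timestamp else 3
    if len(fields) < min_fields:
        raise ExchangeError(f"too few fields ({len(fields)})")
    ts = fields.pop(0) if has_timestamp else None
    site, block, scan = fields[0], fields[1], fields[2]
    payload = []
    for token in fields[3:]:
        key, sep, value = token.partition("=")
        if not sep:
            raise ExchangeError(f"payload token {token!r} is not key=value")
        payload.append((key, _parse_value(value)))
    try:
        return ExchangeMessage(
            site_id=site,
            block_index=int(block),
            scan_index=int(scan),
            payload=tuple(payload),
            timestamp=ts,
        )
    except ValueError as exc:
        raise ExchangeError(f"non-integer block/scan index: {exc}") from exc


def exchange_due(scan_index: int, channel: OutputChannelSpec) -> bool:
    """True iff the block-local scan index is one of the channel's trigger
    scans (cwOutputScan / cwReceiveScan)."""
    return scan_index in channel.trigger_scans


def write_message(
    platform: ExchangePlatform, channel: OutputChannelSpec, msg: ExchangeMessage
) -> str:
    """Append (or overwrite, per channel mode) one message line; returns the
    exact line written as the acknowledgement."""
    if not channel.state:
        raise ExchangeError(f"channel for site {channel.site_id!r} is inactive")
    allowed = set(channel.output_params)
    bad = [k for k, _ in msg.payload if k not in allowed]
    if bad:
        raise ExchangeError(f"payload keys {bad} not in configured params {sorted(allowed)}")
    if msg.scan_index not in channel.trigger_scans:
        raise ExchangeError(
            f"scan {msg.scan_index} is not a trigger scan {list(channel.trigger_scans)}"
        )
    line = format_message(msg, write_timestamp=channel.write_timestamp)
    path = platform.path_for(channel)
    mode = "a" if channel.mode == "append" else "w"
    with open(path, mode, encoding="utf-8", newline="") as fh:
        fh.write(line)
    return line


@dataclass
class ReadResult:
    messages: list[ExchangeMessage]
    cursor: int
    errors: list[tuple[int, str]] = field(default_factory=list)


def read_messages(
    platform: ExchangePlatform, channel: ReceiveChannelSpec, since: int = 0
) -> ReadResult:
    """Poll the channel file for complete messages after byte cursor
    ``since``.  Partial trailing lines stay unread until the next poll;
    malformed complete lines are reported per line number and skipped."""
    if not channel.state:
        raise ExchangeError(f"channel for site {channel.site_id!r} is inactive")
    path = platform.path_for(channel)
    if not os.path.exists(path):
        return ReadResult(messages=[], cursor=since)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        fh.seek(since)
        chunk = fh.read()
    end = chunk.rfind("\n")
    if end < 0:
        return ReadResult(messages=[], cursor=since)
    complete, cursor = chunk[: end + 1], since + len(chunk[: end + 1].encode("utf-8"))

    n_before = 0
    messages, errors = [], []
    for i, line in enumerate(complete.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            messages.append(parse_line(line, has_timestamp=channel.write_timestamp))
        except ExchangeError as exc:
            errors.append((n_before + i, str(exc)))
    return ReadResult(messages=messages, cursor=cursor, errors=errors)
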