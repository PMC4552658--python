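"""CSV I/O for progress curves and titrations, plus FASTA reading.

Trace files carry the header ``time_s,abs_390nm`` preceded by optional
``# key=value`` metadata lines serializing the assay conditions;
titration files use ``inhibitor_M,k_per_s`` with an optional
``replicate`` column.  Values are written with 12 significant digits so
a write/read round-trip preserves them to that precision.  Parse errors
name the offending line.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np

from ppikit.assay import AssayConditions, ProgressCurve
from ppikit.inhibition import InhibitionSeries

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_fasta",
]

_TRACE_HEADER = "time_s,abs_390nm"
_FMT = "{:.12g}"

_COND_FLOAT_FIELDS = {
    f.name for f in fields(AssayConditions) if f.type in ("float", float)
}


def write_trace_csv(trace: ProgressCurve, path: str | Path) -> None:
    """Write a trace with its conditions as ``# key=value`` metadata."""
    path = Path(path)
    lines = [f"# provenance={trace.provenance}"]
    for f in fields(AssayConditions):
        lines.append(f"# {f.name}=" + _FMT.format(getattr(trace.conditions, f.name)))
    lines.append(_TRACE_HEADER)
    for t, a in zip(trace.times, trace.absorbances):
        lines.append(_FMT.format(t) + "," + _FMT.format(a))
    path.write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> ProgressCurve:
    """Read a trace CSV; errors name the first offending line."""
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    absorbances: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != _TRACE_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_TRACE_HEADER!r}, "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                t, a = float(cells[0]), float(cells[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in {line!r}") from None
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path}:{lineno}: time {t} not strictly increasing "
                    f"(previous {times[-1]})"
                )
            times.append(t)
            absorbances.append(a)
    if not header_seen:
        raise ValueError(f"{path}: no header line found")
    if not times:
        raise ValueError(f"{path}: no data rows")
    cond_kwargs = {
        k: float(v) for k, v in meta.items() if k in _COND_FLOAT_FIELDS
    }
    conditions = AssayConditions(**cond_kwargs) if cond_kwargs else AssayConditions()
    return ProgressCurve(
        np.array(times), np.array(absorbances), conditions,
        provenance=meta.get("provenance", "measured"),
    )


def write_titration_csv(series: InhibitionSeries, path: str | Path) -> None:
    """Write a titration; replicates (when present) get one row each."""
    path = Path(path)
    lines = [
        f"# inhibitor_name={series.inhibitor_name}",
        "# k0=" + _FMT.format(series.k0),
        "# ku=" + _FMT.format(series.ku),
    ]
    if series.replicates is not None and any(len(r) > 1 for r in series.replicates):
        lines.append("inhibitor_M,k_per_s,replicate")
        for conc, reps in zip(series.concentrations, series.replicates):
            for j, k in enumerate(reps, start=1):
                lines.append(_FMT.format(conc) + "," + _FMT.format(k) + f",{j}")
    else:
        lines.append("inhibitor_M,k_per_s")
        for conc, k in zip(series.concentrations, series.rate_constants):
            lines.append(_FMT.format(conc) + "," + _FMT.format(k))
    path.write_text("\n".join(lines) + "\n")


def read_titration_csv(
    path: str | Path, k0: float | None = None, ku: float | None = None
) -> InhibitionSeries:
    """Read a titration CSV; metadata k0/ku can be overridden by args."""
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[float, float, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = line.split(",")
            if header is None:
                if cells[:2] != ["inhibitor_M", "k_per_s"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting "
                        f"'inhibitor_M,k_per_s', got {line!r}"
                    )
                header = cells
                continue
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            try:
                conc, k = float(cells[0]), float(cells[1])
                rep = int(cells[2]) if len(cells) > 2 else 1
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in {line!r}") from None
            rows.append((conc, k, rep))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if k0 is None:
        if "k0" not in meta:
            raise ValueError(f"{path}: k0 not in metadata and not supplied")
        k0 = float(meta["k0"])
    if ku is None:
        if "ku" not in meta:
            raise ValueError(f"{path}: ku not in metadata and not supplied")
        ku = float(meta["ku"])
    # group replicate rows by concentration, preserving first-seen order
    by_conc: dict[float, list[float]] = {}
    order: list[float] = []
    for conc, k, _rep in rows:
        if conc not in by_conc:
            by_conc[conc] = []
            order.append(conc)
        by_conc[conc].append(k)
    concs = np.array(order)
    means = np.array([float(np.mean(by_conc[c])) for c in order])
    has_reps = any(len(by_conc[c]) > 1 for c in order)
    return InhibitionSeries(
        inhibitor_name=meta.get("inhibitor_name", path.stem),
        concentrations=concs,
        rate_constants=means,
        k0=k0,
        ku=ku,
        replicates=tuple(tuple(by_conc[c]) for c in order) if has_reps else None,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA as (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
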