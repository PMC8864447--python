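"""TSV serialization of spike rasters and PSTH matrices.

Two plain-text dialects (UTF-8, tab-separated, '.' decimal):

* Raster TSV — header ``unit_id layer condition stimulus intensity trial
  spike_time_ms``, one spike per row.  Leading ``#`` comment lines declare
  per-unit metadata (``n_intensities``, per-intensity ``n_trials``,
  ``window_ms``) so that silent trials and spike-free units survive a
  round trip; when absent, the structure is inferred from the maximum
  indices present.
* PSTH TSV — header ``unit_id layer condition stimulus intensity n_trials
  bin_1 .. bin_B``, one row per intensity, rates in Hz at full float
  precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .psth import PSTHMatrix, SpikeRaster

RASTER_COLUMNS = ["unit_id", "layer", "condition", "stimulus",
                  "intensity", "trial", "spike_time_ms"]


def _fmt(x: float) -> str:
    s = format(float(x), ".17g")
    return s


# ---------------------------------------------------------------------------
# rasters

def write_rasters(rasters, path) -> None:
    """Write one or more spike rasters to a single Raster TSV file."""
    if isinstance(rasters, SpikeRaster):
        rasters = [rasters]
    lines = []
    for r in rasters:
        trials = ",".join(str(int(n)) for n in r.n_trials)
        lines.append(
            f"# unit={r.unit_id} layer={r.layer} condition={r.condition} "
            f"stimulus={r.stimulus} n_intensities={r.n_intensities} "
            f"n_trials={trials} window_ms={_fmt(r.window_ms)}"
        )
    lines.append("\t".join(RASTER_COLUMNS))
    for r in rasters:
        ev = r.events
        order = np.lexsort((ev[:, 2], ev[:, 1], ev[:, 0]))
        for i in order:
            z, trial, t = ev[i]
            lines.append(
                f"{r.unit_id}\t{r.layer}\t{r.condition}\t{r.stimulus}\t"
                f"{int(z)}\t{int(trial)}\t{_fmt(t)}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


write_raster = write_rasters


def _parse_meta(line: str) -> dict:
    meta = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_rasters(path) -> list[SpikeRaster]:
    """Read all spike rasters from a Raster TSV file (see module docstring)."""
    path = Path(path)
    meta_by_unit: dict[str, dict] = {}
    header = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                meta = _parse_meta(line)
                if "unit" in meta:
                    meta_by_unit[meta["unit"]] = meta
                continue
            fields = line.split("\t")
            if header is None:
                if fields != RASTER_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: malformed raster header {fields!r}; "
                        f"expected {RASTER_COLUMNS!r}"
                    )
                header = fields
                continue
            if len(fields) != len(RASTER_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(RASTER_COLUMNS)} columns, got {len(fields)}")
            try:
                z = int(fields[4]); trial = int(fields[5]); t = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable numeric field: {exc}")
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            if z < 1 or trial < 1:
                raise ValueError(f"{path}:{lineno}: indices must be >= 1 "
                                 f"(intensity={z}, trial={trial})")
            rows.append((fields[0], fields[1], fields[2], fields[3], z, trial, t, lineno))
    if header is None:
        raise ValueError(f"{path}: missing raster header line")

    units: dict[str, dict] = {}
    for uid, layer, cond, stim, z, trial, t, lineno in rows:
        u = units.setdefault(uid, {"layer": layer, "condition": cond,
                                   "stimulus": stim, "events": [], "line": lineno})
        if (u["layer"], u["condition"], u["stimulus"]) != (layer, cond, stim):
            raise ValueError(f"{path}:{lineno}: metadata for unit {uid!r} is not "
                             f"constant across rows")
        u["events"].append((z, trial, t))
    # units that appear only in metadata comments (spike-free) still count
    for uid, meta in meta_by_unit.items():
        units.setdefault(uid, {"layer": meta.get("layer"),
                               "condition": meta.get("condition"),
                               "stimulus": meta.get("stimulus"),
                               "events": [], "line": 0})

    out = []
    for uid, u in units.items():
        ev = np.array(u["events"], dtype=float).reshape(-1, 3)
        meta = meta_by_unit.get(uid)
        if meta is not None:
            z_n = int(meta["n_intensities"])
            n_trials = np.array([int(x) for x in meta["n_trials"].split(",")])
            window = float(meta.get("window_ms", 50.0))
        else:
            if not len(ev):
                raise ValueError(f"{path}: unit {uid!r} has no events and no "
                                 f"metadata comment declaring its structure")
            z_n = int(ev[:, 0].max())
            n_trials = np.zeros(z_n, dtype=int)
            for z in range(1, z_n + 1):
                sel = ev[:, 0] == z
                n_trials[z - 1] = int(ev[sel, 1].max()) if sel.any() else 0
            window = 50.0
        if len(ev):
            present = set(ev[:, 0].astype(int))
            missing = sorted(set(range(1, max(present) + 1)) - present)
            if meta is None and missing:
                raise ValueError(
                    f"{path}: unit {uid!r}: intensity indices are not contiguous; "
                    f"missing {missing} out of 1..{max(present)}"
                )
            if ev[:, 0].max() > z_n:
                raise ValueError(f"{path}: unit {uid!r}: intensity "
                                 f"{int(ev[:, 0].max())} exceeds declared "
                                 f"n_intensities={z_n}")
        out.append(SpikeRaster(unit_id=uid, layer=u["layer"], condition=u["condition"],
                               stimulus=u["stimulus"], n_intensities=z_n,
                               n_trials=n_trials, events=ev, window_ms=window))
    return out


def read_raster(path) -> SpikeRaster:
    """Read a Raster TSV expected to contain exactly one unit."""
    rasters = read_rasters(path)
    if len(rasters) != 1:
        raise ValueError(f"{path}: expected exactly one unit, found {len(rasters)}")
    return rasters[0]


# ---------------------------------------------------------------------------
# PSTHs

def write_psths(psths, path) -> None:
    """Write one or more PSTH matrices to a PSTH TSV file."""
    if isinstance(psths, PSTHMatrix):
        psths = [psths]
    if not psths:
        raise ValueError("no PSTHs to write")
    n_bins = psths[0].n_bins
    header = (["unit_id", "layer", "condition", "stimulus", "intensity",
               "n_trials"] + [f"bin_{b}" for b in range(1, n_bins + 1)])
    lines = ["\t".join(header)]
    for p in psths:
        if p.n_bins != n_bins:
            raise ValueError("all PSTHs in one file must share the bin count")
        for z in range(p.n_intensities):
            vals = "\t".join(_fmt(v) for v in p.rates[z])
            lines.append(f"{p.unit_id}\t{p.layer}\t{p.condition}\t{p.stimulus}\t"
                         f"{z + 1}\t{int(p.n_trials[z])}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


write_psth = write_psths


def read_psths(path, bin_ms: float = 1.0) -> list[PSTHMatrix]:
    """Read all PSTH matrices from a PSTH TSV file."""
    path = Path(path)
    header = None
    per_unit: dict[str, dict] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if (fields[:6] != ["unit_id", "layer", "condition", "stimulus",
                                   "intensity", "n_trials"]
                        or not all(c.startswith("bin_") for c in fields[6:])
                        or len(fields) < 7):
                    raise ValueError(f"{path}:{lineno}: malformed PSTH header")
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} "
                                 f"columns, got {len(fields)}")
            uid = fields[0]
            u = per_unit.get(uid)
            if u is None:
                u = per_unit[uid] = {"layer": fields[1], "condition": fields[2],
                                     "stimulus": fields[3], "rows": {}}
                order.append(uid)
            z = int(fields[4])
            if z in u["rows"]:
                raise ValueError(f"{path}:{lineno}: duplicate intensity {z} "
                                 f"for unit {uid!r}")
            u["rows"][z] = (int(fields[5]), [float(v) for v in fields[6:]])
    if header is None:
        raise ValueError(f"{path}: missing PSTH header line")
    n_bins = len(header) - 6
    out = []
    for uid in order:
        u = per_unit[uid]
        zs = sorted(u["rows"])
        if zs != list(range(1, len(zs) + 1)):
            missing = sorted(set(range(1, max(zs) + 1)) - set(zs))
            raise ValueError(f"{path}: unit {uid!r}: intensity indices are not "
                             f"contiguous; missing {missing}")
        rates = np.array([u["rows"][z][1] for z in zs])
        n_trials = np.array([u["rows"][z][0] for z in zs])
        out.append(PSTHMatrix(unit_id=uid, layer=u["layer"],
                              condition=u["condition"], stimulus=u["stimulus"],
                              rates=rates, n_trials=n_trials, bin_ms=bin_ms,
                              window_ms=bin_ms * n_bins))
    return out


def read_psth(path, bin_ms: float = 1.0) -> PSTHMatrix:
    """Read a PSTH TSV expected to contain exactly one unit."""
    psths = read_psths(path, bin_ms=bin_ms)
    if len(psths) != 1:
        raise ValueError(f"{path}: expected exactly one unit, found {len(psths)}")
    return psths[0]
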