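"""JCAMP-DX reading and writing for spectra and FIDs.

Two dialects are supported, both in plain AFFN (free-form numeric) encoding:

* ``XYDATA`` — a single real trace ``(X++(Y..Y))``, the common exchange form
  for a processed spectrum (ppm axis);
* ``NTUPLES`` — paged real/imaginary data, used for complex spectra and for
  time-domain FIDs.

Acquisition parameters and the processing log travel in ``##$QNMR...``
private labelled-data-records as JSON, so a file written by this package
round-trips to an identical object. Unknown labelled-data-records found
while reading are preserved verbatim in ``Spectrum.metadata``. Compressed
JCAMP encodings (DIF/DUP/SQZ) are not produced and not accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import FID, AcquisitionParams, Spectrum

__all__ = [
    "JcampParseError",
    "write_spectrum",
    "write_fid",
    "read_jcampdx",
    "export_xy",
]

_FMT = "%.10e"
_VALUES_PER_LINE = 5


class JcampParseError(ValueError):
    """A JCAMP-DX file could not be parsed; the message names the line."""


# ---------------------------------------------------------------- writing


def _data_lines(x: np.ndarray, y: np.ndarray) -> list[str]:
    lines = []
    for start in range(0, len(x), _VALUES_PER_LINE):
        xs = x[start]
        ys = y[start : start + _VALUES_PER_LINE]
        lines.append(
            (_FMT % xs) + " " + " ".join(_FMT % v for v in ys)
        )
    return lines


def _private_records(obj: Spectrum | FID) -> list[str]:
    records = []
    acq = obj.acquisition
    if acq is not None:
        records.append("##$QNMRACQUISITION= " + json.dumps(acq.to_dict()))
    if isinstance(obj, Spectrum):
        if obj.processing_log:
            records.append(
                "##$QNMRPROCESSINGLOG= " + json.dumps(obj.processing_log)
            )
        extra = {
            k: v
            for k, v in obj.metadata.items()
            if k != "jcamp_ldrs" and _json_safe(v)
        }
        if extra:
            records.append("##$QNMRMETADATA= " + json.dumps(extra))
    else:
        prov = {k: v for k, v in obj.provenance.items() if _json_safe(v)}
        if prov:
            records.append("##$QNMRMETADATA= " + json.dumps(prov))
    return records


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def write_spectrum(
    spectrum: Spectrum, path: str | Path, dialect: str = "ntuples", title: str = "qnmr spectrum"
) -> None:
    """Write a spectrum as JCAMP-DX.

    ``dialect='ntuples'`` stores real and imaginary pages; ``'xydata'``
    stores only the real trace.
    """
    if dialect not in ("ntuples", "xydata"):
        raise ValueError("dialect must be 'ntuples' or 'xydata'")
    sf = (
        spectrum.acquisition.spectrometer_frequency_mhz
        if spectrum.acquisition is not None
        else 0.0
    )
    head = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.01",
        "##DATA TYPE= NMR SPECTRUM",
        "##ORIGIN= qnmr",
        "##OWNER= qnmr",
        f"##.OBSERVE FREQUENCY= {sf}",
        "##.OBSERVE NUCLEUS= ^1H",
    ]
    head.extend(_private_records(spectrum))
    n = len(spectrum.ppm)
    body: list[str]
    if dialect == "xydata":
        body = [
            "##XUNITS= PPM",
            "##YUNITS= ARBITRARY UNITS",
            "##XFACTOR= 1.0",
            "##YFACTOR= 1.0",
            f"##FIRSTX= {spectrum.ppm[0]:.10e}",
            f"##LASTX= {spectrum.ppm[-1]:.10e}",
            f"##NPOINTS= {n}",
            "##XYDATA= (X++(Y..Y))",
            *_data_lines(spectrum.ppm, spectrum.real),
        ]
    else:
        body = [
            "##NTUPLES= NMR SPECTRUM",
            "##VAR_NAME= FREQUENCY, SPECTRUM/REAL, SPECTRUM/IMAG",
            "##SYMBOL= X, R, I",
            "##VAR_TYPE= INDEPENDENT, DEPENDENT, DEPENDENT",
            "##VAR_FORM= AFFN, AFFN, AFFN",
            f"##VAR_DIM= {n}, {n}, {n}",
            "##UNITS= PPM, ARBITRARY UNITS, ARBITRARY UNITS",
            "##PAGE= N=1",
            "##DATA TABLE= (X++(R..R)), XYDATA",
            *_data_lines(spectrum.ppm, spectrum.real),
            "##PAGE= N=2",
            "##DATA TABLE= (X++(I..I)), XYDATA",
            *_data_lines(spectrum.ppm, spectrum.imag),
            "##END NTUPLES= NMR SPECTRUM",
        ]
    Path(path).write_text("\n".join(head + body + ["##END="]) + "\n")


def write_fid(fid: FID, path: str | Path, title: str = "qnmr fid") -> None:
    """Write a complex FID as an NTUPLES JCAMP-DX file (time axis in seconds)."""
    n = len(fid.samples)
    t = fid.times_s
    head = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.01",
        "##DATA TYPE= NMR FID",
        "##ORIGIN= qnmr",
        "##OWNER= qnmr",
        f"##.OBSERVE FREQUENCY= {fid.acquisition.spectrometer_frequency_mhz}",
        "##.OBSERVE NUCLEUS= ^1H",
    ]
    head.extend(_private_records(fid))
    body = [
        "##NTUPLES= NMR FID",
        "##VAR_NAME= TIME, FID/REAL, FID/IMAG",
        "##SYMBOL= X, R, I",
        "##VAR_TYPE= INDEPENDENT, DEPENDENT, DEPENDENT",
        "##VAR_FORM= AFFN, AFFN, AFFN",
        f"##VAR_DIM= {n}, {n}, {n}",
        "##UNITS= SECONDS, ARBITRARY UNITS, ARBITRARY UNITS",
        "##PAGE= N=1",
        "##DATA TABLE= (X++(R..R)), XYDATA",
        *_data_lines(t, fid.samples.real),
        "##PAGE= N=2",
        "##DATA TABLE= (X++(I..I)), XYDATA",
        *_data_lines(t, fid.samples.imag),
        "##END NTUPLES= NMR FID",
    ]
    Path(path).write_text("\n".join(head + body + ["##END="]) + "\n")


def export_xy(spectrum: Spectrum, path: str | Path) -> None:
    """Plain two-column text export: ppm and real intensity."""
    with open(path, "w") as fh:
        fh.write("# ppm intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.real):
            fh.write(f"{x:.10e} {y:.10e}\n")


# ---------------------------------------------------------------- reading


def _parse_ldrs(text: str, path: str) -> list[tuple[str, str, int]]:
    """Split a JCAMP file into (label, value, first_line_number) records."""
    records: list[tuple[str, str, int]] = []
    label = None
    value_lines: list[str] = []
    start_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if line.startswith("##"):
            if label is not None:
                records.append((label, "\n".join(value_lines), start_line))
            if "=" not in line:
                raise JcampParseError(
                    f"{path}:{lineno}: labelled-data-record without '='"
                )
            label, _, rest = line[2:].partition("=")
            label = label.strip().upper()
            value_lines = [rest.strip()]
            start_line = lineno
        else:
            if label is None:
                if line.strip():
                    raise JcampParseError(
                        f"{path}:{lineno}: data before any labelled-data-record"
                    )
                continue
            value_lines.append(line)
    if label is not None:
        records.append((label, "\n".join(value_lines), start_line))
    return records


def _parse_table(value: str, path: str, lineno: int) -> tuple[np.ndarray, np.ndarray]:
    """Parse an AFFN (X++(Y..Y)) block into x (anchors expanded) and y arrays."""
    lines = [ln for ln in value.splitlines()[1:] if ln.strip()]
    if not lines:
        raise JcampParseError(f"{path}:{lineno}: empty data table")
    xs: list[float] = []
    ys: list[float] = []
    anchors: list[tuple[int, float]] = []  # (index into ys, x value)
    for off, ln in enumerate(lines, start=1):
        tokens = ln.split()
        try:
            values = [float(tok) for tok in tokens]
        except ValueError as exc:
            raise JcampParseError(
                f"{path}:{lineno + off}: malformed numeric value ({exc})"
            ) from None
        if len(values) < 2:
            raise JcampParseError(
                f"{path}:{lineno + off}: data line needs an x value and at "
                "least one y value"
            )
        anchors.append((len(ys), values[0]))
        ys.extend(values[1:])
    # reconstruct the full x axis by linear interpolation between anchors
    n = len(ys)
    if len(anchors) == 1:
        step = 0.0
    else:
        (i0, x0), (i1, x1) = anchors[0], anchors[1]
        step = (x1 - x0) / (i1 - i0) if i1 != i0 else 0.0
    x = np.empty(n)
    for k, (idx, xval) in enumerate(anchors):
        end = anchors[k + 1][0] if k + 1 < len(anchors) else n
        x[idx:end] = xval + step * np.arange(end - idx)
    return x, np.asarray(ys)


def read_jcampdx(path: str | Path) -> FID | Spectrum:
    """Read a JCAMP-DX file written in the XYDATA or NTUPLES dialect.

    Returns a :class:`FID` for ``DATA TYPE= NMR FID`` files and a
    :class:`Spectrum` otherwise. Raises :class:`JcampParseError` with the
    offending line number on malformed input.
    """
    path = Path(path)
    text = path.read_text()
    records = _parse_ldrs(text, str(path))
    labels = [label for label, _, _ in records]
    if "END" not in labels:
        raise JcampParseError(f"{path}: truncated file (missing ##END=)")

    def first(label: str) -> str | None:
        for lab, val, _ in records:
            if lab == label:
                return val.splitlines()[0] if val else ""
        return None

    acq = None
    acq_json = first("$QNMRACQUISITION")
    if acq_json:
        acq = AcquisitionParams.from_dict(json.loads(acq_json))
    metadata_json = first("$QNMRMETADATA")
    metadata = json.loads(metadata_json) if metadata_json else {}
    log_json = first("$QNMRPROCESSINGLOG")
    processing_log = (
        [(step, params) for step, params in json.loads(log_json)] if log_json else []
    )
    data_type = (first("DATA TYPE") or "").upper()

    known = {
        "TITLE", "JCAMP-DX", "DATA TYPE", "ORIGIN", "OWNER", "END",
        ".OBSERVE FREQUENCY", ".OBSERVE NUCLEUS", "XUNITS", "YUNITS",
        "XFACTOR", "YFACTOR", "FIRSTX", "LASTX", "NPOINTS", "XYDATA",
        "NTUPLES", "VAR_NAME", "SYMBOL", "VAR_TYPE", "VAR_FORM", "VAR_DIM",
        "UNITS", "PAGE", "DATA TABLE", "END NTUPLES", "$QNMRACQUISITION",
        "$QNMRPROCESSINGLOG", "$QNMRMETADATA", "DATA CLASS",
    }
    unknown = {
        lab: val for lab, val, _ in records if lab not in known
    }
    if unknown:
        metadata["jcamp_ldrs"] = unknown

    tables = [
        (val, lineno) for lab, val, lineno in records if lab == "DATA TABLE"
    ]
    if tables:
        x_real, real = _parse_table(tables[0][0], str(path), tables[0][1])
        if len(tables) > 1:
            _, imag = _parse_table(tables[1][0], str(path), tables[1][1])
            if len(imag) != len(real):
                raise JcampParseError(
                    f"{path}: real and imaginary pages have different lengths"
                )
        else:
            imag = np.zeros_like(real)
        if "FID" in data_type:
            if acq is None:
                raise JcampParseError(
                    f"{path}: FID file lacks the acquisition record needed to "
                    "reconstruct dwell time"
                )
            return FID(
                samples=real + 1j * imag,
                dwell_time_s=acq.dwell_time_s,
                acquisition=acq,
                provenance=metadata,
            )
        return Spectrum(
            real=real,
            imag=imag,
            ppm=x_real,
            acquisition=acq,
            processing_log=processing_log,
            metadata=metadata,
        )

    xy = [(val, lineno) for lab, val, lineno in records if lab == "XYDATA"]
    if not xy:
        raise JcampParseError(f"{path}: no XYDATA or DATA TABLE block found")
    x, y = _parse_table(xy[0][0], str(path), xy[0][1])
    npoints = first("NPOINTS")
    if npoints is not None and int(float(npoints)) != len(y):
        raise JcampParseError(
            f"{path}: NPOINTS={npoints} but {len(y)} values were read"
        )
    return Spectrum(
        real=y,
        imag=np.zeros_like(y),
        ppm=x,
        acquisition=acq,
        processing_log=processing_log,
        metadata=metadata,
    )
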