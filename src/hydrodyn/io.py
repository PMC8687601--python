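"""Plain-text readers/writers for the pipeline's file interfaces."""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .transients import DecayFit, Transient

__all__ = ["read_transient_tsv", "read_transient_dir", "read_spectrum_tsv",
           "write_fits_json", "read_fits_json", "write_summary_tsv"]

_WL_RE = re.compile(r"(\d{3})(?:nm)?\.tsv$")


def read_transient_tsv(path, wavelength: float | None = None, window: str = "upconversion",
                       irf_fwhm: float | None = None) -> Transient:
    """Read a two-column (time_ps, intensity) TSV; wavelength from name if absent."""
    path = Path(path)
    if wavelength is None:
        m = _WL_RE.search(path.name)
        if not m:
            raise ValueError(f"cannot infer wavelength from {path.name!r}")
        wavelength = float(m.group(1))
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    t, y = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    return Transient(wavelength=wavelength, t=t, intensity=y,
                     window=window, irf_fwhm=irf_fwhm)


def read_transient_dir(directory, pattern: str = "*.tsv", **kw) -> list:
    paths = sorted(Path(directory).glob(pattern))
    transients = [read_transient_tsv(p, **kw) for p in paths if _WL_RE.search(p.name)]
    return sorted(transients, key=lambda tr: tr.wavelength)


def read_spectrum_tsv(path):
    from .fres import Spectrum

    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return Spectrum(wavelength=df.iloc[:, 0].to_numpy(float),
                    intensity=df.iloc[:, 1].to_numpy(float))


def write_fits_json(fits, path):
    records = [
        {
            "wavelength": f.wavelength,
            "solvation_terms": f.solvation_terms,
            "lifetime_terms": f.lifetime_terms,
            "irf_fwhm": f.irf_fwhm,
            "gof": f.gof,
            "flags": f.flags,
        }
        for f in fits
    ]
    Path(path).write_text(json.dumps(records, indent=2, default=float))


def read_fits_json(path) -> list:
    records = json.loads(Path(path).read_text())
    return [
        DecayFit(
            wavelength=r["wavelength"],
            solvation_terms=[tuple(p) for p in r["solvation_terms"]],
            lifetime_terms=[tuple(p) for p in r["lifetime_terms"]],
            irf_fwhm=r["irf_fwhm"], gof=r["gof"], flags=list(r.get("flags", [])),
        )
        for r in records
    ]


def write_summary_tsv(summaries, path):
    rows = []
    for s in summaries:
        row = {"site": s.site, "state": s.state, "lambda_peak_nm": s.lambda_peak}
        for i in range(3):
            row[f"tau_S{i+1}_ps"] = s.tau_s[i]
            row[f"f_{i+1}"] = s.fractions[i]
            row[f"S_{i+1}_cm-1_per_ps"] = s.speeds_s[i]
        for i in range(2):
            row[f"tau_W{i+2}_ps"] = s.tau_w[i]
            row[f"theta_{i+2}_deg"] = s.theta[i]
            row[f"omega_{i+2}_deg_per_ps"] = s.omega[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
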