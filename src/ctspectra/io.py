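"""Readers for epoch data and PSD tables.

Real recordings enter the pipeline either as delimited numeric tables
(samples x channels, optional header naming the channels) or as EDF/BDF
files via MNE when that optional dependency is installed.  Everything
downstream works on plain arrays, so nothing here is required for the
synthetic pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_epoch_table", "read_edf", "read_psd_table",
           "write_feature_table"]


def read_epoch_table(path: str | Path, fs: float) -> tuple:
    """Read a delimited epoch table.

    Accepts comma/whitespace-delimited text with one row per sample and
    one column per channel; a header row of channel names is detected
    automatically.  Returns ``(data, channel_names)`` with data shaped
    (n_channels, n_samples).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    try:  # header row of numbers means there was no header
        names = [str(c) for c in df.columns]
        [float(n) for n in names]
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        names = [f"ch{k}" for k in range(df.shape[1])]
    except ValueError:
        pass
    data = df.to_numpy(dtype=float).T
    if data.size == 0:
        raise ValueError(f"{path}: empty epoch table")
    return data, names


def read_edf(path: str | Path) -> tuple:
    """Read an EDF/BDF recording via MNE (optional dependency).

    Returns ``(data, channel_names, fs)``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF/BDF requires the optional 'mne' dependency "
            "(pip install ctspectra[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error") \
        if str(path).lower().endswith(".edf") else \
        mne.io.read_raw_bdf(str(path), preload=True, verbose="error")
    return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])


def read_psd_table(path: str | Path) -> dict:
    """Read a long-format PSD table (freq_hz, power, epoch_id[, channel]).

    Returns ``{(epoch_id, channel): (freqs, power)}``; channel is "" when
    the column is absent.
    """
    df = pd.read_csv(path)
    required = {"freq_hz", "power", "epoch_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "channel" not in df.columns:
        df["channel"] = ""
    out = {}
    for (epoch, chan), grp in df.groupby(["epoch_id", "channel"]):
        grp = grp.sort_values("freq_hz")
        out[(epoch, chan)] = (grp["freq_hz"].to_numpy(),
                              grp["power"].to_numpy())
    return out


def write_feature_table(fits: dict, path: str | Path) -> pd.DataFrame:
    """Write per-epoch spectral features as a flat CSV.

    ``fits`` maps epoch id to a :class:`~ctspectra.spectral.SpectralFit`.
    """
    from .spectral import select_alpha

    rows = []
    for epoch_id, fit in fits.items():
        alpha = select_alpha(fit)
        rows.append({
            "epoch_id": epoch_id,
            "offset": fit.aperiodic.offset,
            "exponent": fit.aperiodic.exponent,
            "alpha_power": alpha.power if alpha else np.nan,
            "alpha_cf": alpha.center if alpha else np.nan,
            "n_peaks": len(fit.peaks),
            "r2": fit.r_squared,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
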