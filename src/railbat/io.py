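"""CSV / YAML / WAV input-output with fixed column schemas.

Schemas
-------
bat-call log:  ``timestamp_s, species, feeding_buzz``
train log:     ``start_s, end_s, track, n_cars, overlap``
site config:   YAML mapping of SiteConfig fields
SPL curve:     ``time_s, spl_db``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .event_processing import TrainPass
from .synthetic_data import SiteConfig

CALL_COLUMNS = ["timestamp_s", "species", "feeding_buzz"]
TRAIN_COLUMNS = ["start_s", "end_s", "track", "n_cars", "overlap"]


def write_call_log(path, times, species, buzz) -> None:
    pd.DataFrame({"timestamp_s": times, "species": species,
                  "feeding_buzz": np.asarray(buzz, dtype=bool)}).to_csv(path, index=False)


def read_call_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call log missing columns: {sorted(missing)}")
    return df.sort_values("timestamp_s").reset_index(drop=True)


def write_train_log(path, trains: list[TrainPass]) -> None:
    pd.DataFrame([{"start_s": t.start_s, "end_s": t.end_s, "track": t.track,
                   "n_cars": t.n_cars, "overlap": t.overlap}
                  for t in trains]).to_csv(path, index=False)


def read_train_log(path) -> list[TrainPass]:
    df = pd.read_csv(path)
    missing = set(TRAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"train log missing columns: {sorted(missing)}")
    return [TrainPass(start_s=r.start_s, end_s=r.end_s, track=int(r.track),
                      n_cars=int(r.n_cars), overlap=bool(r.overlap))
            for r in df.sort_values("start_s").itertuples()]


def write_site_config(path, cfg: SiteConfig) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in cfg.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(d))


def read_site_config(path) -> SiteConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "detector_train_distance" in d:
        d["detector_train_distance"] = tuple(d["detector_train_distance"])
    return SiteConfig(**d)


def write_wav(path, waveform, sample_rate: float) -> None:
    """Write a float waveform (|x| <= 1) as 16-bit PCM mono."""
    x = np.asarray(waveform, dtype=float)
    if np.max(np.abs(x), initial=0.0) > 1.0:
        raise ValueError("waveform clips; scale below full scale first")
    wavfile.write(path, int(sample_rate), np.round(x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read PCM WAV to float in [-1, 1]."""
    sr, x = wavfile.read(path)
    if x.dtype == np.int16:
        x = x / 32768.0
    elif x.dtype == np.int32:
        x = x / 2147483648.0
    elif x.dtype == np.uint8:
        x = (x.astype(float) - 128.0) / 128.0
    else:
        x = x.astype(float)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return x, float(sr)
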