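"""Dataset and result file I/O.

Presence-background datasets travel as plain CSV: a header row, an
``s`` column (1 = presence sample, 0 = background), covariate columns
``x1..xd``, and an optional ``y_latent`` column carrying the simulated
truth of background rows.  Comma separator, UTF-8, ``.`` decimal;
floats are written with 17 significant digits so a round trip is
bit-exact.  Provenance goes to a sidecar JSON next to the CSV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import PBDataset

_FLOAT_FMT = "%.17g"


def write_pb_csv(data: PBDataset, path: str | Path) -> None:
    path = Path(path)
    d = data.n_covariates
    cols = {"s": np.concatenate([np.ones(data.n1, int), np.zeros(data.n0, int)])}
    X = np.vstack([data.P, data.B])
    for j in range(d):
        cols[f"x{j + 1}"] = X[:, j]
    if data.y_latent is not None:
        y = np.full(data.n1 + data.n0, "", dtype=object)
        y[data.n1:] = data.y_latent
        cols["y_latent"] = y
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if data.provenance:
        path.with_suffix(".provenance.json").write_text(
            json.dumps(data.provenance, indent=2, default=str))


def read_pb_csv(path: str | Path) -> PBDataset:
    """Parse a presence-background CSV; malformed rows are rejected
    with their line numbers."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "s" not in df.columns:
        raise ValueError(f"{path}: missing required column 's'")
    xcols = [c for c in df.columns if c.startswith("x")]
    if not xcols:
        raise ValueError(f"{path}: no covariate columns (x1, x2, ...)")
    s = df["s"]
    bad = df.index[~s.isin([0, 1])]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-binary 's' on line(s) "
                         f"{[int(i) + 2 for i in bad[:10]]}")
    Xdf = df[xcols].apply(pd.to_numeric, errors="coerce")
    bad = df.index[Xdf.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric covariates on line(s) "
                         f"{[int(i) + 2 for i in bad[:10]]}")
    X = Xdf.to_numpy(float)
    mask = s.to_numpy() == 1
    y_latent = None
    if "y_latent" in df.columns:
        yb = pd.to_numeric(df.loc[~mask, "y_latent"], errors="coerce")
        if yb.notna().all():
            y_latent = yb.to_numpy(int)
    prov_path = path.with_suffix(".provenance.json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return PBDataset(P=X[mask], B=X[~mask], y_latent=y_latent, provenance=prov)


@dataclass
class RunManifest:
    """Stamp written alongside every CLI run for reproducibility."""

    command: str
    config_digest: str
    seed: Optional[int]
    package_version: str
    started: str
    outputs: list

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def make_manifest(command: str, config: dict, seed: Optional[int],
                  outputs: list) -> RunManifest:
    from . import __version__
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return RunManifest(command=command, config_digest=digest, seed=seed,
                       package_version=__version__,
                       started=time.strftime("%Y-%m-%dT%H:%M:%S"),
                       outputs=[str(o) for o in outputs])
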