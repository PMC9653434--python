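"""Key-value text configuration for default parameters and tolerances.

The format is one ``key = value`` pair per line; ``#`` starts a comment.
Values are parsed as int, then float, then bool, then left as strings.
"""

from __future__ import annotations

from .errors import InvalidParameterError

DEFAULTS: dict[str, object] = {
    # rate model
    "odor_input": 10.0,
    "w_sac_gc": 1.0,
    "dt": 0.01,
    "t_end": 100.0,
    "divergence_bound": 1e6,
    # two-photon pipeline
    "r_threshold": 0.65,
    "max_shift_fraction": 0.10,
    "n_pcs": 10,
    "roi_pcs": 3,
    "roi_coefficient_threshold": 0.25,
    "smooth_window": 5,
    "alpha_light": 0.01,
    "alpha_odor": 0.05,
    # photometry
    "f0_window_s": 2.0,
    "impact_window_s": 1.0,
    "qc_threshold": 0.01,
    "target_rate": 500.0,
    # population stats
    "min_cells": 5,
}


def _coerce(raw: str) -> object:
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def load_config(path=None) -> dict[str, object]:
    """Defaults, optionally overridden by a key = value text file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            cfg[key.strip()] = _coerce(raw)
    return cfg
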