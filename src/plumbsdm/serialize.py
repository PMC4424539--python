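"""Versioned model-file serialization (joblib payload + metadata envelope)."""

from __future__ import annotations

import joblib

FORMAT = "plumbsdm-model"
FORMAT_VERSION = 1


def save_model(fit, path) -> None:
    """Write a fitted occurrence or abundance model to *path*.

    The envelope records the format version, the model class and the
    covariate list, so a file describes itself without being unpickled
    blindly into the wrong reader.
    """
    payload = {
        "format": FORMAT,
        "format_version": FORMAT_VERSION,
        "model_class": type(fit).__name__,
        "covariates": list(fit.covariates),
        "fit": fit,
    }
    joblib.dump(payload, path)


def load_model(path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != FORMAT:
        raise ValueError(f"{path} is not a recognised model file")
    if payload.get("format_version", 0) > FORMAT_VERSION:
        raise ValueError(
            f"{path} uses model format v{payload['format_version']}, "
            f"newer than this reader (v{FORMAT_VERSION})"
        )
    return payload["fit"]
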