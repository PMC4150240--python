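"""Accessors for the data files shipped with the package.

The comparison table and demo model are *synthetic*: the table is the linear
decile binning from :func:`obcval.comparison.default_comparison_table`, and
the demo model was trained on a generated cohort — neither reproduces any
published calibration or previously trained classifier.
"""

from __future__ import annotations

from importlib.resources import as_file, files


def _data_path(name: str):
    return files("obcval") / "data" / name


def shipped_config():
    """The fully populated default :class:`~obcval.AlgorithmConfig`."""
    from .config import AlgorithmConfig
    with as_file(_data_path("default_config.yaml")) as path:
        return AlgorithmConfig.from_yaml(path)


def shipped_comparison_table():
    """The synthetic default comparison table shipped for tests and demos."""
    from .comparison import load_comparison_table
    with as_file(_data_path("comparison_table_synthetic.yaml")) as path:
        return load_comparison_table(path)


def shipped_demo_model():
    """The demo ADTree model, trained on a synthetic cohort."""
    from .adtree import load_model
    with as_file(_data_path("demo_model_synthetic.json")) as path:
        return load_model(path)
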