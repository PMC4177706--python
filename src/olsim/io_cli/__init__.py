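"""Configuration, seed management, writers and the command-line interface."""

from .rngs import derive_rng, stream_label, stream_seed
from .writers import RunManifest, write_edges, write_manifest, write_table

_CONFIG_NAMES = {"load_unit_config", "load_timeseries_config", "read_config_mapping"}


def __getattr__(name):
    # config imports experiments, which imports this package; resolve lazily
    # to keep the import graph acyclic.
    if name in _CONFIG_NAMES:
        from . import config

        return getattr(config, name)
    raise AttributeError(name)

__all__ = [
    "load_unit_config",
    "load_timeseries_config",
    "read_config_mapping",
    "derive_rng",
    "stream_seed",
    "stream_label",
    "RunManifest",
    "write_table",
    "write_edges",
    "write_manifest",
]
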