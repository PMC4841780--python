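"""Input/output, configuration and command-line entry points.

This subpackage owns every external format used by the pipeline: plate
layouts and colony tables (TSV), annotation tables and interaction-network
edge lists, Cluster 3.0 ``.cdt``/``.gtr``/``.atr`` exports, the declarative
YAML configuration, and the ``spiscreen`` CLI.
"""

from spiscreen.io_cli.layout import (
    CONDITIONS,
    CONTROL_PREFIX,
    AnnotationError,
    InteractionNetwork,
    PlateLayout,
    read_annotation_table,
    write_annotation_table,
)
from spiscreen.io_cli.tables import (
    ColonyTableError,
    read_colony_table,
    read_score_table,
    write_colony_table,
    write_score_table,
)
from spiscreen.io_cli.cdt import read_cdt, write_cdt
from spiscreen.io_cli.config import ConfigError, load_config


def run_pipeline(config_path):
    """Lazy proxy for :func:`spiscreen.io_cli.pipeline.run_pipeline` (the
    pipeline pulls in the simulator, which itself uses this package)."""
    from spiscreen.io_cli.pipeline import run_pipeline as _run

    return _run(config_path)

__all__ = [
    "CONDITIONS",
    "CONTROL_PREFIX",
    "AnnotationError",
    "ColonyTableError",
    "ConfigError",
    "InteractionNetwork",
    "PlateLayout",
    "load_config",
    "read_annotation_table",
    "read_cdt",
    "read_colony_table",
    "read_score_table",
    "run_pipeline",
    "write_annotation_table",
    "write_cdt",
    "write_colony_table",
    "write_score_table",
]
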