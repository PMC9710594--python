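"""Exception hierarchy used across the package."""


class CodesError(Exception):
    """Base class for all package-specific errors."""


class PDBFormatError(CodesError):
    """Input file could not be parsed as PDB."""


class PartitionError(CodesError):
    """Receptor/ligand chain partition is missing, overlapping or incomplete."""


class EmptySelectionError(CodesError):
    """An atom/residue selection matched nothing."""


class CorrespondenceError(CodesError):
    """Coordinate arrays cannot be put in atom-wise correspondence."""


class UndefinedNativeError(CodesError):
    """The native contact map is empty, so fnat is undefined."""


class DegenerateStatisticsError(CodesError):
    """Too few observations to compute the requested statistic."""


class KeyCollisionError(CodesError):
    """Duplicate (target_id, model_id) keys with conflicting values."""


class SchemaError(CodesError):
    """A feature table does not carry the columns a model requires."""


class DegenerateLabelError(CodesError):
    """Training labels contain a single class."""


class ManifestError(CodesError):
    """A target-metadata manifest is inconsistent or incomplete."""


class ConfigError(CodesError):
    """A run configuration file is invalid."""
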