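"""Exception hierarchy for the pipeline."""


class EvmirnaError(Exception):
    """Base class for all package errors."""


class SchemaError(EvmirnaError):
    """A required column is missing or a field violates the canonical schema."""


class DuplicateWellError(EvmirnaError):
    """The same (sample_id, assay_id) appears more than once in a well table."""


class ConsistencyError(EvmirnaError):
    """Two inputs that must agree (e.g. well table vs sample sheet) do not."""


class ConfigError(EvmirnaError):
    """An invalid configuration value or reference."""


class NoNormalizersError(EvmirnaError):
    """No assay satisfied the endogenous-normalizer criteria.

    The pipeline refuses to fall back silently; pass an explicit
    ``override`` list of assay ids to :func:`evmirna.normalize.select_normalizers`
    if a manual normalizer set is appropriate.
    """


class DisconnectedDesignError(EvmirnaError):
    """The incomplete block design splits into disconnected treatment groups."""
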