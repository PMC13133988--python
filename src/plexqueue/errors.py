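"""Exception hierarchy for the pipeline.

Exit-status mapping used by the CLI: usage errors -> 1, data errors
(anything derived from DataError) -> 2, BackendUnavailableError -> 3.
"""


class PlexQueueError(Exception):
    """Base class for all pipeline errors."""


class DataError(PlexQueueError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file does not follow the expected format."""


class DomainError(PlexQueueError):
    """An argument is outside the operation's domain."""


class SchedulerError(PlexQueueError):
    """Queue state machine violation (bad transition, sequencing error)."""


class SchemaVersionError(PlexQueueError):
    """The job store was written by an incompatible schema version."""

    def __init__(self, found: str, supported: str):
        self.found = found
        self.supported = supported
        super().__init__(
            f"job store schema version {found} is newer than supported version "
            f"{supported}; refusing to open"
        )


class BackendUnavailableError(PlexQueueError):
    """The requested prediction engine cannot be invoked in this environment."""
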