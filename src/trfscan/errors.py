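"""Exception hierarchy shared by all pipeline stages.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class TrfscanError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(TrfscanError):
    """Invalid configuration: bad value ranges, unknown keys, missing fields."""


class DataError(TrfscanError):
    """Invalid or inconsistent input data (malformed files, bad coordinates)."""


class FastqParseError(DataError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index
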