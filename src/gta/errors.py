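"""Exception hierarchy: input errors exit with code 2, runtime errors with 3."""


class GTAError(Exception):
    """Base class for all package errors."""


class InputError(GTAError):
    """Malformed or inconsistent user input (files, labels, parameters)."""
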