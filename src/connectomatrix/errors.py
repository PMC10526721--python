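"""Exception hierarchy shared across the package."""


class ConnectomatrixError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ConnectomatrixError):
    """A registry or curation configuration file is malformed or inconsistent
    (duplicate codes, dangling references, missing required fields)."""


class UnknownUnitError(ConnectomatrixError, KeyError):
    """A parcellation-unit code is not present in the registry."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"unknown parcellation unit code: {self.code!r}"


class UnknownPathwayError(ConnectomatrixError, KeyError):
    """A pathway name (or synonym) is not present in the evidence database."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:
        return f"unknown pathway: {self.name!r}"


class TypologyError(ConnectomatrixError, ValueError):
    """An asserted connection violates the distance-type rule system."""


class CompatibilityError(ConnectomatrixError):
    """Two objects built against different registries (or eras) were combined."""
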