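"""Exception types shared across the toolkit."""


class XRNavError(Exception):
    """Base class for all toolkit errors."""


class InvalidGeometryError(XRNavError, ValueError):
    """C-arm geometry violates a physical or vendor-range constraint."""


class NotProjectableError(XRNavError, ValueError):
    """Point at or behind the focal spot: projective depth <= 0."""


class DegenerateGeometryError(XRNavError, ValueError):
    """View configuration too close to parallel for triangulation."""


class DegenerateFitError(XRNavError, ValueError):
    """Point configuration insufficient for a rigid fit (n<3 or collinear)."""


class MissingTagError(XRNavError, ValueError):
    """Mandatory DICOM geometry tags absent from a dataset."""

    def __init__(self, tags):
        self.tags = list(tags)
        super().__init__(f"missing mandatory DICOM geometry tags: {', '.join(self.tags)}")


class UnsupportedFormatError(XRNavError, ValueError):
    """File is not in a supported format (e.g. XML VTK instead of legacy)."""
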