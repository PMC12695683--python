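"""Exception hierarchy for the pipeline.

All exceptions derive from :class:`RTImageRiskError` so callers can catch
package-level failures with a single except clause; the finer classes map
onto the distinct failure modes of DICOM parsing, grid algebra and the
parameter registry.
"""


class RTImageRiskError(Exception):
    """Base class for all package errors."""


class DicomFormatError(RTImageRiskError):
    """A DICOM file is malformed or missing a mandatory tag."""


class DicomTypeError(RTImageRiskError):
    """A DICOM file has the wrong modality/SOP class for the requested read."""


class GridMismatchError(RTImageRiskError):
    """Two grids that must share a lattice or frame of reference do not."""


class EmptyMaskError(RTImageRiskError):
    """A rasterized ROI contains no voxels."""


class ROINotFoundError(RTImageRiskError, KeyError):
    """Requested ROI name absent from a structure set."""


class ParameterError(RTImageRiskError, ValueError):
    """A model or operation parameter is out of its valid domain."""


class RegistrySchemaError(RTImageRiskError):
    """The radiobiological parameter registry violates its schema."""
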