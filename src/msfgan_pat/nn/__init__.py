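"""A compact numpy autodiff engine and the layers built on it."""

import ctypes as _ctypes


def _tune_allocator():
    """Raise glibc's mmap/trim thresholds.

    Training allocates many short-lived multi-megabyte arrays; with the
    default thresholds each one is mmap'ed and unmapped again, and the
    resulting page-fault churn dominates elementwise op time.  Serving
    them from the retained heap removes that cost.  Best effort: silently
    skipped on non-glibc platforms.
    """
    try:
        libc = _ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)   # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from . import autograd
from .autograd import Tensor, grad, no_grad
from .layers import (Module, Conv2d, SNConv2d, BatchNorm2d, PReLU, Dense,
                     power_iteration_sigma)
from .optim import Adam

__all__ = [
    "autograd", "Tensor", "grad", "no_grad", "Module", "Conv2d", "SNConv2d",
    "BatchNorm2d", "PReLU", "Dense", "power_iteration_sigma", "Adam",
]
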