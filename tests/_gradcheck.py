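"""Finite-difference gradient checking for the autodiff ops."""

import numpy as np

from cropseg.autodiff import Tensor


def numeric_grad(fn, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar fn at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = fn()
        flat[i] = orig - h
        fm = fn()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * h)
    return g


def check_op(build, inputs: dict, rtol: float = 1e-5, atol: float = 1e-7):
    """Compare analytic and numeric gradients of a scalar-valued graph.

    ``inputs`` maps names to float64 arrays; ``build`` receives the matching
    Tensors (requires_grad=True) and returns a scalar Tensor.
    """
    tensors = {k: Tensor(v.copy(), requires_grad=True) for k, v in inputs.items()}
    out = build(**tensors)
    out.backward()
    for name, t in tensors.items():
        def value():
            fresh = {k: Tensor(tt.data, requires_grad=False) for k, tt in tensors.items()}
            return float(build(**fresh).data)

        num = numeric_grad(value, t.data)
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        np.testing.assert_allclose(ana, num, rtol=rtol, atol=atol,
                                   err_msg=f"gradient mismatch for input {name!r}")
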