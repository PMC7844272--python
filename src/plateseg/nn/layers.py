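"""Parameterized layers built on the autodiff core.

Every convolution and transposed convolution carries a bias and is followed by
a ReLU when used inside a block (the predictor 1x1x1 convolutions feed a
softmax instead).  Trainable variables are Xavier-uniform initialized from a
caller-supplied generator and tagged with the parameter-subset name used by
the regularized loss: ``theta_2d``, ``theta_3d``, ``theta_2dp`` or
``theta_3dp``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag


class Parameter(ag.Tensor):
    """A trainable tensor with a stable name and a parameter-subset tag."""

    __slots__ = ("name", "group")

    def __init__(self, data: np.ndarray, name: str, group: str):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.group = group


def xavier_uniform(
    shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base: recursively collects Parameters from attributes and sub-modules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = {p.name: p for p in self.parameters()}
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict does not match network parameters: {missing}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            p.data = state[name].astype(np.float32).copy()


class Conv3d(Module):
    """Zero-padded shape-preserving convolution + bias."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: tuple[int, int, int],
        name: str,
        group: str,
        rng: np.random.Generator,
    ):
        k = int(np.prod(kernel))
        self.kernel = kernel
        self.w = Parameter(
            xavier_uniform((cout, cin) + tuple(kernel), cin * k, cout * k, rng),
            f"{name}.w",
            group,
        )
        self.b = Parameter(np.zeros(cout, dtype=np.float32), f"{name}.b", group)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return ag.conv3d(x, self.w, self.b)


class ConvTranspose(Module):
    """Transposed convolution with kernel == stride (integer upsampling)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        factors: tuple[int, int, int],
        name: str,
        group: str,
        rng: np.random.Generator,
    ):
        k = int(np.prod(factors))
        self.factors = factors
        self.w = Parameter(
            xavier_uniform((cout, cin) + tuple(factors), cin, cout * k, rng),
            f"{name}.w",
            group,
        )
        self.b = Parameter(np.zeros(cout, dtype=np.float32), f"{name}.b", group)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return ag.conv_transpose(x, self.w, self.b, self.factors)
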