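"""Unit helpers.

Everything inside the package is SI (m, N, Pa, s).  Reports and some
conventional quantities use nm, nN and MPa; in particular the indenter profile
coefficient ``c`` of ``h_c = c * a**n`` is conventionally quoted with lengths
expressed in micrometres (units um**(1 - n)), so explicit converters are
provided.
"""

NM = 1e-9
UM = 1e-6
NN = 1e-9
MPA = 1e6


def c_si_to_um(c_si: float, n: float) -> float:
    """Convert a profile coefficient ``c`` from SI (m**(1-n)) to um**(1-n).

    ``h_c = c a**n`` with both lengths in metres maps to
    ``h_c[um] = c' a[um]**n`` with ``c' = c * (1e6)**(1 - n)``.
    """
    return c_si * (1e6) ** (1.0 - n)


def c_um_to_si(c_um: float, n: float) -> float:
    """Inverse of :func:`c_si_to_um`."""
    return c_um * (1e-6) ** (1.0 - n)
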