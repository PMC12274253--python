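"""Independent reference formulas used as test oracles.

``case1_sequential`` transcribes the published step-by-step competition
formulas for the generalist-only operation case (young generalists compete
for x; then old generalists for the x left over, then for x1, then for x2),
including the free/hidden nutrient bookkeeping.  It is kept deliberately
literal — nested min/max expressions, no vectorization — so that it stays an
independent check on the package's product-of-fractions operator.
"""


def case1_sequential(qt01, qt02, qx, qx1, qx2):
    """Return (QT01, QT02, free, hidden) for an only-generalist time point."""
    qtot = qt01 + qt02

    if qt01 == 0 or qx == 0:
        QT01 = 0.0
    else:
        QT01 = min(qt01 * qx / qtot, qt01)

    # In exact arithmetic qx - QT01 >= 0 always; the share QT01 = qt01*qx/qtot
    # can overshoot qx by one rounding step when qt02 = 0, so clamp.
    QT02_x = max(min(qx - QT01, qt02), 0.0)
    if QT02_x == 0 or qx1 == 0:
        QT02_x_x1 = 0.0
    else:
        QT02_x_x1 = min(QT02_x * qx1 / qt02, QT02_x)
    if QT02_x_x1 == 0 or qx2 == 0:
        QT02 = 0.0
    else:
        QT02 = min(QT02_x_x1 * qx2 / qt02, QT02_x_x1)

    free = (
        max(qx - qtot, 0.0),
        max(qx1 - qt02, 0.0),
        max(qx2 - qt02, 0.0),
    )
    hidden = (
        min(qx - QT01, qt02) - QT02,
        min(qx1, qt02) - QT02,
        min(qx2, qt02) - QT02,
    )
    return QT01, QT02, free, hidden
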