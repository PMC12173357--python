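"""Independent minimal VMD used only as a cross-check oracle in tests.

A direct transcription of the classic alternating-direction scheme
(even-mirror extension, full-loop updates, no shared code with the package
implementation). Deliberately kept naive: its only job is to provide an
independently coded answer for center-frequency agreement tests.
"""

import numpy as np


def vmd_reference(x, fs, K, alpha=2000.0, tau=0.0, tol=1e-7, max_iter=500):
    """Return (modes, center_freqs_hz) sorted by ascending center frequency."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    # classic even mirror extension of half the signal at each end
    f = np.concatenate([x[: N // 2][::-1], x, x[N - N // 2 :][::-1]])
    T = len(f)
    t = np.arange(1, T + 1) / T
    freqs = t - 0.5 - 1.0 / T

    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0

    omega = np.zeros((max_iter + 1, K))
    omega[0] = (0.5 / K) * np.arange(K)
    lam = np.zeros((max_iter + 1, T), dtype=complex)
    u_hat_plus = np.zeros((max_iter + 1, T, K), dtype=complex)

    n = 0
    udiff = tol + 1e300
    while udiff > tol and n < max_iter - 1:
        k = 0
        sum_uk = u_hat_plus[n, :, K - 1] + np.sum(u_hat_plus[n, :, :-1], axis=1) \
            - u_hat_plus[n, :, 0]
        u_hat_plus[n + 1, :, k] = (f_hat_plus - sum_uk - lam[n] / 2) / (
            1 + alpha * 2 * (freqs - omega[n, k]) ** 2
        )
        omega[n + 1, k] = np.dot(
            freqs[T // 2 :], np.abs(u_hat_plus[n + 1, T // 2 :, k]) ** 2
        ) / np.sum(np.abs(u_hat_plus[n + 1, T // 2 :, k]) ** 2)
        for k in range(1, K):
            sum_uk = u_hat_plus[n + 1, :, k - 1] + sum_uk - u_hat_plus[n, :, k]
            u_hat_plus[n + 1, :, k] = (f_hat_plus - sum_uk - lam[n] / 2) / (
                1 + alpha * 2 * (freqs - omega[n, k]) ** 2
            )
            omega[n + 1, k] = np.dot(
                freqs[T // 2 :], np.abs(u_hat_plus[n + 1, T // 2 :, k]) ** 2
            ) / np.sum(np.abs(u_hat_plus[n + 1, T // 2 :, k]) ** 2)
        lam[n + 1] = lam[n] + tau * (np.sum(u_hat_plus[n + 1], axis=1) - f_hat_plus)
        n += 1
        udiff = np.spacing(1.0)
        for k in range(K):
            diff = u_hat_plus[n, :, k] - u_hat_plus[n - 1, :, k]
            udiff += (1.0 / T) * np.real(np.dot(diff, np.conj(diff)))
        udiff = float(np.abs(udiff))

    omega_final = omega[n]
    u_hat = np.zeros((T, K), dtype=complex)
    u_hat[T // 2 :, :] = u_hat_plus[n, T // 2 :, :]
    u_hat[T // 2 : 0 : -1, :] = np.conj(u_hat_plus[n, T // 2 :, :])
    u_hat[0, :] = np.conj(u_hat[-1, :])
    u = np.zeros((K, T))
    for k in range(K):
        u[k] = np.real(np.fft.ifft(np.fft.ifftshift(u_hat[:, k])))
    u = u[:, T // 4 : 3 * T // 4]

    order = np.argsort(omega_final)
    return u[order], np.clip(omega_final[order], 0, 0.5) * fs
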