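species,Hh,Lr,Ss,Rt,Mp1,Sc,Gj,Am,Pa1,Mm,Sh,Lc,Ip,Mp2,Ia,Ts,Pa2,En,Sl,Rc,Sg,It
Lr,0.46,,,,,,,,,,,,,,,,,,,,,
Ss,0.40,0.77,,,,,,,,,,,,,,,,,,,,
Rt,0.14,0.61,0.78,,,,,,,,,,,,,,,,,,,
Mp1,0.70,0.51,0.53,0.25,,,,,,,,,,,,,,,,,,
Sc,0.45,0.78,0.83,0.66,0.68,,,,,,,,,,,,,,,,,
Gj,0.43,0.69,0.80,0.74,0.58,0.76,,,,,,,,,,,,,,,,
Am,0.27,0.69,0.82,0.72,0.50,0.82,0.71,,,,,,,,,,,,,,,
Pa1,0.64,0.49,0.47,0.19,0.53,0.43,0.52,0.38,,,,,,,,,,,,,,
Mm,0.39,0.29,0.38,0.28,0.58,0.58,0.42,0.40,0.25,,,,,,,,,,,,,
Sh,0.17,0.48,0.54,0.43,0.28,0.38,0.29,0.51,0.20,0.16,,,,,,,,,,,,
Lc,0.28,0.48,0.54,0.39,0.27,0.50,0.46,0.55,0.27,0.28,0.26,,,,,,,,,,,
Ip,0.52,0.78,0.76,0.56,0.72,0.76,0.67,0.70,0.52,0.41,0.43,0.42,,,,,,,,,,
Mp2,0.39,0.53,0.55,0.22,0.45,0.48,0.52,0.44,0.58,0.22,0.37,0.31,0.46,,,,,,,,,
Ia,0.19,0.34,0.52,0.32,0.39,0.49,0.35,0.48,0.29,0.37,0.63,0.19,0.36,0.62,,,,,,,,
Ts,0.70,0.49,0.53,0.32,0.74,0.65,0.53,0.39,0.51,0.55,0.31,0.36,0.56,0.42,0.47,,,,,,,
Pa2,0.15,0.33,0.40,0.32,0.32,0.51,0.42,0.38,0.16,0.19,0.07,0.12,0.42,0.27,0.13,0.20,,,,,,
En,0.31,0.56,0.65,0.45,0.46,0.52,0.41,0.53,0.27,0.48,0.54,0.44,0.63,0.33,0.44,0.38,0.10,,,,,
Sl,0.18,0.24,0.22,0.73,0.22,0.22,0.21,0.16,0.18,0.07,0.30,0.07,0.24,0.47,0.20,0.18,0.06,0.13,,,,
Rc,0.50,0.24,0.25,0.12,0.58,0.46,0.28,0.27,0.30,0.68,0.06,0.42,0.40,0.17,0.13,0.48,0.06,0.29,0.04,,,
Sg,0.41,0.56,0.66,0.69,0.52,0.71,0.65,0.62,0.30,0.54,0.42,0.30,0.69,0.24,0.40,0.63,0.33,0.42,0.14,0.41,,
It,0.56,0.53,0.56,0.38,0.46,0.51,0.49,0.37,0.40,0.28,0.32,0.30,0.50,0.44,0.39,0.59,0.02,0.37,0.17,0.42,0.53,
As,0.28,0.56,0.49,0.41,0.35,0.51,0.38,0.49,0.24,0.25,0.37,0.26,0.56,0.34,0.30,0.38,0.11,0.43,0.39,0.12,0.53,0.37
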