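pattern_id	pattern
subfamily1	EFF[IM]YAH[DE][QR]RGY[FY][AT]FWQxM[DE]NA[HY]xGS[DN][IM]LVVT[LV]TN[DEG][EQ]Sx[HR][IV]E[ANS]Qx[DN]x[DE]T[LM]
subfamily2	T[DEK][IV]xV[LP]RWxS[DN][KR]F[FY]xG[ST][FY]SNxP[IV]GV[DNS][HR]x[EGQ][FHY][DN]x[IL][KR]APVGx(3)[FY]x[GT][EG][EH]x[ST][AEQS]
subfamily3	V[FV]E[AG]G[ADGNST]R[AIV]GGR[IV]x[ST]x[EQ]Fx[AGS]x(2)[IV]ExGATW[IV]xGx(1,2)Gx(1,2)P[ILV][HY]x[ILM][AS]x[DEQ]x(3)[FL]
subfamily4	LHG[AV][CGS]x[DE]N[PS][LV][AS]x(2)Ix(2)LxLx[IL]YxT[CGS]x[DG][DN]S[IV][IL][FY][DE]HDL[EK]Sx(2)[IL][FY][DN]x(2)Gx(2)[IV][EPS]
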