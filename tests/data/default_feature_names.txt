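GAAC.G1
GAAC.G2
GAAC.G3
GAAC.G4
GAAC.G5
DPC.AA
DPC.AC
DPC.AD
DPC.AE
DPC.AF
DPC.AG
DPC.AH
DPC.AI
DPC.AK
DPC.AL
DPC.AM
DPC.AN
DPC.AP
DPC.AQ
DPC.AR
DPC.AS
DPC.AT
DPC.AV
DPC.AW
DPC.AY
DPC.CA
DPC.CC
DPC.CD
DPC.CE
DPC.CF
DPC.CG
DPC.CH
DPC.CI
DPC.CK
DPC.CL
DPC.CM
DPC.CN
DPC.CP
DPC.CQ
DPC.CR
DPC.CS
DPC.CT
DPC.CV
DPC.CW
DPC.CY
DPC.DA
DPC.DC
DPC.DD
DPC.DE
DPC.DF
DPC.DG
DPC.DH
DPC.DI
DPC.DK
DPC.DL
DPC.DM
DPC.DN
DPC.DP
DPC.DQ
DPC.DR
DPC.DS
DPC.DT
DPC.DV
DPC.DW
DPC.DY
DPC.EA
DPC.EC
DPC.ED
DPC.EE
DPC.EF
DPC.EG
DPC.EH
DPC.EI
DPC.EK
DPC.EL
DPC.EM
DPC.EN
DPC.EP
DPC.EQ
DPC.ER
DPC.ES
DPC.ET
DPC.EV
DPC.EW
DPC.EY
DPC.FA
DPC.FC
DPC.FD
DPC.FE
DPC.FF
DPC.FG
DPC.FH
DPC.FI
DPC.FK
DPC.FL
DPC.FM
DPC.FN
DPC.FP
DPC.FQ
DPC.FR
DPC.FS
DPC.FT
DPC.FV
DPC.FW
DPC.FY
DPC.GA
DPC.GC
DPC.GD
DPC.GE
DPC.GF
DPC.GG
DPC.GH
DPC.GI
DPC.GK
DPC.GL
DPC.GM
DPC.GN
DPC.GP
DPC.GQ
DPC.GR
DPC.GS
DPC.GT
DPC.GV
DPC.GW
DPC.GY
DPC.HA
DPC.HC
DPC.HD
DPC.HE
DPC.HF
DPC.HG
DPC.HH
DPC.HI
DPC.HK
DPC.HL
DPC.HM
DPC.HN
DPC.HP
DPC.HQ
DPC.HR
DPC.HS
DPC.HT
DPC.HV
DPC.HW
DPC.HY
DPC.IA
DPC.IC
DPC.ID
DPC.IE
DPC.IF
DPC.IG
DPC.IH
DPC.II
DPC.IK
DPC.IL
DPC.IM
DPC.IN
DPC.IP
DPC.IQ
DPC.IR
DPC.IS
DPC.IT
DPC.IV
DPC.IW
DPC.IY
DPC.KA
DPC.KC
DPC.KD
DPC.KE
DPC.KF
DPC.KG
DPC.KH
DPC.KI
DPC.KK
DPC.KL
DPC.KM
DPC.KN
DPC.KP
DPC.KQ
DPC.KR
DPC.KS
DPC.KT
DPC.KV
DPC.KW
DPC.KY
DPC.LA
DPC.LC
DPC.LD
DPC.LE
DPC.LF
DPC.LG
DPC.LH
DPC.LI
DPC.LK
DPC.LL
DPC.LM
DPC.LN
DPC.LP
DPC.LQ
DPC.LR
DPC.LS
DPC.LT
DPC.LV
DPC.LW
DPC.LY
DPC.MA
DPC.MC
DPC.MD
DPC.ME
DPC.MF
DPC.MG
DPC.MH
DPC.MI
DPC.MK
DPC.ML
DPC.MM
DPC.MN
DPC.MP
DPC.MQ
DPC.MR
DPC.MS
DPC.MT
DPC.MV
DPC.MW
DPC.MY
DPC.NA
DPC.NC
DPC.ND
DPC.NE
DPC.NF
DPC.NG
DPC.NH
DPC.NI
DPC.NK
DPC.NL
DPC.NM
DPC.NN
DPC.NP
DPC.NQ
DPC.NR
DPC.NS
DPC.NT
DPC.NV
DPC.NW
DPC.NY
DPC.PA
DPC.PC
DPC.PD
DPC.PE
DPC.PF
DPC.PG
DPC.PH
DPC.PI
DPC.PK
DPC.PL
DPC.PM
DPC.PN
DPC.PP
DPC.PQ
DPC.PR
DPC.PS
DPC.PT
DPC.PV
DPC.PW
DPC.PY
DPC.QA
DPC.QC
DPC.QD
DPC.QE
DPC.QF
DPC.QG
DPC.QH
DPC.QI
DPC.QK
DPC.QL
DPC.QM
DPC.QN
DPC.QP
DPC.QQ
DPC.QR
DPC.QS
DPC.QT
DPC.QV
DPC.QW
DPC.QY
DPC.RA
DPC.RC
DPC.RD
DPC.RE
DPC.RF
DPC.RG
DPC.RH
DPC.RI
DPC.RK
DPC.RL
DPC.RM
DPC.RN
DPC.RP
DPC.RQ
DPC.RR
DPC.RS
DPC.RT
DPC.RV
DPC.RW
DPC.RY
DPC.SA
DPC.SC
DPC.SD
DPC.SE
DPC.SF
DPC.SG
DPC.SH
DPC.SI
DPC.SK
DPC.SL
DPC.SM
DPC.SN
DPC.SP
DPC.SQ
DPC.SR
DPC.SS
DPC.ST
DPC.SV
DPC.SW
DPC.SY
DPC.TA
DPC.TC
DPC.TD
DPC.TE
DPC.TF
DPC.TG
DPC.TH
DPC.TI
DPC.TK
DPC.TL
DPC.TM
DPC.TN
DPC.TP
DPC.TQ
DPC.TR
DPC.TS
DPC.TT
DPC.TV
DPC.TW
DPC.TY
DPC.VA
DPC.VC
DPC.VD
DPC.VE
DPC.VF
DPC.VG
DPC.VH
DPC.VI
DPC.VK
DPC.VL
DPC.VM
DPC.VN
DPC.VP
DPC.VQ
DPC.VR
DPC.VS
DPC.VT
DPC.VV
DPC.VW
DPC.VY
DPC.WA
DPC.WC
DPC.WD
DPC.WE
DPC.WF
DPC.WG
DPC.WH
DPC.WI
DPC.WK
DPC.WL
DPC.WM
DPC.WN
DPC.WP
DPC.WQ
DPC.WR
DPC.WS
DPC.WT
DPC.WV
DPC.WW
DPC.WY
DPC.YA
DPC.YC
DPC.YD
DPC.YE
DPC.YF
DPC.YG
DPC.YH
DPC.YI
DPC.YK
DPC.YL
DPC.YM
DPC.YN
DPC.YP
DPC.YQ
DPC.YR
DPC.YS
DPC.YT
DPC.YV
DPC.YW
DPC.YY
PSETS.slice1.mean.A
PSETS.slice1.mean.R
PSETS.slice1.mean.N
PSETS.slice1.mean.D
PSETS.slice1.mean.C
PSETS.slice1.mean.Q
PSETS.slice1.mean.E
PSETS.slice1.mean.G
PSETS.slice1.mean.H
PSETS.slice1.mean.I
PSETS.slice1.mean.L
PSETS.slice1.mean.K
PSETS.slice1.mean.M
PSETS.slice1.mean.F
PSETS.slice1.mean.P
PSETS.slice1.mean.S
PSETS.slice1.mean.T
PSETS.slice1.mean.W
PSETS.slice1.mean.Y
PSETS.slice1.mean.V
PSETS.slice2.mean.A
PSETS.slice2.mean.R
PSETS.slice2.mean.N
PSETS.slice2.mean.D
PSETS.slice2.mean.C
PSETS.slice2.mean.Q
PSETS.slice2.mean.E
PSETS.slice2.mean.G
PSETS.slice2.mean.H
PSETS.slice2.mean.I
PSETS.slice2.mean.L
PSETS.slice2.mean.K
PSETS.slice2.mean.M
PSETS.slice2.mean.F
PSETS.slice2.mean.P
PSETS.slice2.mean.S
PSETS.slice2.mean.T
PSETS.slice2.mean.W
PSETS.slice2.mean.Y
PSETS.slice2.mean.V
PSETS.slice3.mean.A
PSETS.slice3.mean.R
PSETS.slice3.mean.N
PSETS.slice3.mean.D
PSETS.slice3.mean.C
PSETS.slice3.mean.Q
PSETS.slice3.mean.E
PSETS.slice3.mean.G
PSETS.slice3.mean.H
PSETS.slice3.mean.I
PSETS.slice3.mean.L
PSETS.slice3.mean.K
PSETS.slice3.mean.M
PSETS.slice3.mean.F
PSETS.slice3.mean.P
PSETS.slice3.mean.S
PSETS.slice3.mean.T
PSETS.slice3.mean.W
PSETS.slice3.mean.Y
PSETS.slice3.mean.V
SGACT.seg1.lag1.A
SGACT.seg1.lag1.R
SGACT.seg1.lag1.N
SGACT.seg1.lag1.D
SGACT.seg1.lag1.C
SGACT.seg1.lag1.Q
SGACT.seg1.lag1.E
SGACT.seg1.lag1.G
SGACT.seg1.lag1.H
SGACT.seg1.lag1.I
SGACT.seg1.lag1.L
SGACT.seg1.lag1.K
SGACT.seg1.lag1.M
SGACT.seg1.lag1.F
SGACT.seg1.lag1.P
SGACT.seg1.lag1.S
SGACT.seg1.lag1.T
SGACT.seg1.lag1.W
SGACT.seg1.lag1.Y
SGACT.seg1.lag1.V
SGACT.seg2.lag1.A
SGACT.seg2.lag1.R
SGACT.seg2.lag1.N
SGACT.seg2.lag1.D
SGACT.seg2.lag1.C
SGACT.seg2.lag1.Q
SGACT.seg2.lag1.E
SGACT.seg2.lag1.G
SGACT.seg2.lag1.H
SGACT.seg2.lag1.I
SGACT.seg2.lag1.L
SGACT.seg2.lag1.K
SGACT.seg2.lag1.M
SGACT.seg2.lag1.F
SGACT.seg2.lag1.P
SGACT.seg2.lag1.S
SGACT.seg2.lag1.T
SGACT.seg2.lag1.W
SGACT.seg2.lag1.Y
SGACT.seg2.lag1.V
SGACT.seg3.lag1.A
SGACT.seg3.lag1.R
SGACT.seg3.lag1.N
SGACT.seg3.lag1.D
SGACT.seg3.lag1.C
SGACT.seg3.lag1.Q
SGACT.seg3.lag1.E
SGACT.seg3.lag1.G
SGACT.seg3.lag1.H
SGACT.seg3.lag1.I
SGACT.seg3.lag1.L
SGACT.seg3.lag1.K
SGACT.seg3.lag1.M
SGACT.seg3.lag1.F
SGACT.seg3.lag1.P
SGACT.seg3.lag1.S
SGACT.seg3.lag1.T
SGACT.seg3.lag1.W
SGACT.seg3.lag1.Y
SGACT.seg3.lag1.V
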