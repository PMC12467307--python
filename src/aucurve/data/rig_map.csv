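au_id,facs_description,channels
AU1,Inner brow raiser,CTRL_L_brow_raiseIn;CTRL_R_brow_raiseIn
AU2,Outer brow raiser,CTRL_L_brow_raiseOut;CTRL_R_brow_raiseOut
AU4,Brow lowerer,CTRL_L_brow_down;CTRL_R_brow_down;CTRL_L_brow_lateral;CTRL_R_brow_lateral
AU5,Upper lid raiser,CTRL_L_eye_eyelidU;CTRL_R_eye_eyelidU
AU6,Cheek raiser,CTRL_L_eye_cheekRaise;CTRL_R_eye_cheekRaise
AU7,Lid tightener,CTRL_L_eye_squintInner;CTRL_R_eye_squintInner
AU9,Nose wrinkler,CTRL_L_nose;CTRL_R_nose;CTRL_R_nose_wrinkleUpper;CTRL_L_nose_wrinkleUpper
AU10,Upper lip raiser,CTRL_L_mouth_upperLipRaise;CTRL_R_mouth_upperLipRaise
AU12,Lip corner puller,CTRL_L_mouth_cornerPull;CTRL_R_mouth_cornerPull
AU15,Lip corner depressor,CTRL_L_mouth_cornerDepress;CTRL_R_mouth_cornerDepress
AU20,Lip stretcher,CTRL_L_mouth_stretch;CTRL_R_mouth_stretch
AU23,Lip tightener,CTRL_L_mouth_tightenU;CTRL_R_mouth_tightenU;CTRL_L_mouth_tightenD;CTRL_R_mouth_tightenD
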