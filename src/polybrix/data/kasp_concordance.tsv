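sample	position	sequencing	kasp
ORUS 4540A	Ro01:14978562	A:T	A:T
ORUS 4540A	Ro01:14978613	AC:GT	AC:GT
ORUS 4540A	Ro01:14979298	T:A	T:A
ORUS 4647U	Ro01:14978562	A:A	A:A
ORUS 4647U	Ro01:14978613	AC:AC	AC:AC
ORUS 4647U	Ro01:14979298	T:T	T:T
ORUS 4674C	Ro01:14978562	A:T	T:T
ORUS 4674C	Ro01:14978613	AC:GT	GT:GT
ORUS 4674C	Ro01:14979298	T:A	T:A
Marion	Ro01:14978562	A:T	A:T
Marion	Ro01:14978613	AC:GT	AC:GT
Marion	Ro01:14979298	T:A	T:A
Nightfall	Ro01:14978562	A:A	A:A
Nightfall	Ro01:14978613	AC:AC	AC:AC
Nightfall	Ro01:14979298	T:T	T:T
Waldo	Ro01:14978562	A:G	A:A
Waldo	Ro01:14978613	AC:AC	AC:AC
Waldo	Ro01:14979298	T:T	T:T
Bassettberry	Ro01:14978562	A:G	A:A
Bassettberry	Ro01:14978613	AC:AA	AC:AC
Bassettberry	Ro01:14979298	T:T	T:T
ORUS 4647L	Ro01:14978562	A:A	A:A
ORUS 4647L	Ro01:14978613	AC:AC	AC:AC
ORUS 4647L	Ro01:14979298	T:T	T:T
ORUS 4647M	Ro01:14978562	A:A	A:A
ORUS 4647M	Ro01:14978613	AC:AC	AC:AC
ORUS 4647M	Ro01:14979298	T:T	T:T
ORUS 4647R	Ro01:14978562	A:A	A:A
ORUS 4647R	Ro01:14978613	AC:AC	AC:AC
ORUS 4647R	Ro01:14979298	T:T	T:T
Silvan	Ro01:14978562	A:A	A:A
Silvan	Ro01:14978613	AC:AA	AC:AC
Silvan	Ro01:14979298	T:T	T:T
Osage	Ro01:14978562	A:T	A:T
Osage	Ro01:14978613	AC:GT	AC:GT
Osage	Ro01:14979298	T:A	T:A
A-2487T	Ro01:14978562	A:T	T:T
A-2487T	Ro01:14978613	AC:GT	GT:GT
A-2487T	Ro01:14979298	T:A	A:A
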